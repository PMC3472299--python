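"""UPRE promoter-motif scanning and gene-set enrichment.

The unfolded-protein-response element (UPRE) bound by HacA is a short
palindromic, degenerate consensus — here written as the IUPAC 11-mer
``CANRNTGKCCT`` (from the alternation notation CAN(G/A)NTGT/GCCT).
The analysis extracts a fixed window upstream of each gene's start
codon, scans both strands for exact degenerate matches, and tests
whether a study set (e.g. consistently up-regulated genes) is enriched
for motif-positive promoters with a one-sided Fisher's exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "MotifPattern",
    "PromoterSet",
    "MotifHit",
    "ContingencyTable",
    "MotifEnrichmentResult",
    "parse_iupac",
    "extract_upstream",
    "scan_promoters",
    "fisher_exact_one_sided",
    "motif_enrichment",
]

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}
_SET_TO_CODE = {v: k for k, v in IUPAC_CODES.items()}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class MotifPattern:
    """Degenerate consensus as a canonical IUPAC string plus per-position sets."""

    iupac: str
    allowed: tuple[frozenset[str], ...]

    def __len__(self) -> int:
        return len(self.iupac)

    @property
    def reverse_complement(self) -> "MotifPattern":
        rc_sets = tuple(
            frozenset(_COMPLEMENT[b] for b in s) for s in reversed(self.allowed)
        )
        return MotifPattern("".join(_SET_TO_CODE[s] for s in rc_sets), rc_sets)


@dataclass
class PromoterSet:
    """Upstream sequences per gene, 5'->3' toward the start codon.

    ``full_window`` records whether the complete requested window was
    retrievable (False where a contig edge truncated it).
    """

    sequences: dict[str, str]
    full_window: dict[str, bool] = field(default_factory=dict)
    window: int | None = None

    def __post_init__(self) -> None:
        for gene, seq in self.sequences.items():
            seq = seq.upper()
            if set(seq) - set("ACGTN"):
                bad = sorted(set(seq) - set("ACGTN"))
                raise ValueError(f"promoter of {gene!r} has invalid characters {bad}")
            self.sequences[gene] = seq
        for gene in self.sequences:
            self.full_window.setdefault(gene, True)

    @property
    def genes(self) -> set[str]:
        return set(self.sequences)


@dataclass(frozen=True)
class MotifHit:
    gene: str
    offset: int  # 0-based on the stored (plus) promoter sequence
    strand: str  # "+" or "-"
    matched: str  # the matched word as stored on the plus sequence


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: rows in-set / not-in-set, columns motif-positive / -negative."""

    a: int  # in set, positive
    b: int  # in set, negative
    c: int  # not in set, positive
    d: int  # not in set, negative

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")


@dataclass
class MotifEnrichmentResult:
    table: ContingencyTable
    p_value: float
    odds_ratio: float
    positives_in_set: int
    hits: list[MotifHit]
    positive_genes: set[str]


def parse_iupac(pattern: str) -> MotifPattern:
    """Parse a degenerate consensus, normalizing alternation notation.

    Accepts plain IUPAC strings as well as single-position alternations
    written ``(G/A)`` or as a bare ``X/Y`` between two bases, so the
    literature form ``CAN(G/A)NTGT/GCCT`` canonicalizes to
    ``CANRNTGKCCT``.
    """
    if not pattern:
        raise ValueError("empty motif pattern")
    pattern = pattern.strip().upper()
    allowed: list[frozenset[str]] = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "(":
            close = pattern.find(")", i)
            if close < 0:
                raise ValueError(f"unclosed '(' at position {i} in {pattern!r}")
            group = pattern[i + 1 : close].split("/")
            bases: set[str] = set()
            for alt in group:
                if alt not in IUPAC_CODES:
                    raise ValueError(
                        f"invalid code {alt!r} in alternation at position {i}"
                    )
                bases |= IUPAC_CODES[alt]
            allowed.append(frozenset(bases))
            i = close + 1
        elif ch == "/":
            # bare X/Y alternation: merge with the previous position
            if not allowed or i + 1 >= len(pattern):
                raise ValueError(f"misplaced '/' at position {i} in {pattern!r}")
            nxt = pattern[i + 1]
            if nxt not in IUPAC_CODES:
                raise ValueError(f"invalid code {nxt!r} at position {i + 1}")
            allowed[-1] = allowed[-1] | IUPAC_CODES[nxt]
            i += 2
        elif ch in IUPAC_CODES:
            allowed.append(IUPAC_CODES[ch])
            i += 1
        else:
            raise ValueError(f"invalid IUPAC code {ch!r} at position {i}")
    canonical = "".join(_SET_TO_CODE[s] for s in allowed)
    return MotifPattern(canonical, tuple(allowed))


def extract_upstream(
    genome: dict[str, str],
    annotation: pd.DataFrame,
    window: int = 400,
) -> PromoterSet:
    """Extract the upstream window of each gene, 5'->3' toward the start.

    ``annotation`` needs columns ``gene_id, contig, start, end, strand``
    with 1-based inclusive coordinates (GFF3 convention).  For plus-strand
    genes the window lies immediately 5' of ``start`` on the plus strand;
    for minus-strand genes it is the reverse complement of the window
    immediately 3' of ``end``.  Windows truncated by a contig edge are
    returned shortened with ``full_window`` False; genes with no
    retrievable sequence are omitted with a warning.
    """
    sequences: dict[str, str] = {}
    full: dict[str, bool] = {}
    for rec in annotation.itertuples(index=False):
        contig = str(rec.contig)
        if contig not in genome:
            raise KeyError(f"contig {contig!r} of gene {rec.gene_id!r} not in genome")
        seq = genome[contig].upper()
        if rec.strand == "+":
            end0 = int(rec.start) - 1  # exclusive end in 0-based coords
            start0 = max(0, end0 - window)
            upstream = seq[start0:end0]
        elif rec.strand == "-":
            start0 = int(rec.end)  # 0-based start just past the gene
            end0 = min(len(seq), start0 + window)
            upstream = str(Seq(seq[start0:end0]).reverse_complement())
        else:
            raise ValueError(f"gene {rec.gene_id!r} has invalid strand {rec.strand!r}")
        if not upstream:
            logger.warning("gene %s has a zero-length upstream window; omitted", rec.gene_id)
            continue
        sequences[str(rec.gene_id)] = upstream
        full[str(rec.gene_id)] = len(upstream) == window
    return PromoterSet(sequences, full, window=window)


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _match_table(motif: MotifPattern) -> np.ndarray:
    # 5 columns: A C G T N; N in the sequence matches no motif position
    table = np.zeros((len(motif), 5), dtype=bool)
    for j, s in enumerate(motif.allowed):
        for b in s:
            table[j, _BASE_INDEX[b]] = True
    return table


def _scan_one(seq: str, table: np.ndarray) -> np.ndarray:
    L = table.shape[0]
    n = len(seq)
    if n < L:
        return np.empty(0, dtype=int)
    enc = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    idx = np.full(n, 4, dtype=np.int8)
    for base, k in _BASE_INDEX.items():
        idx[enc == ord(base)] = k
    ok = np.ones(n - L + 1, dtype=bool)
    for j in range(L):
        ok &= table[j, idx[j : j + n - L + 1]]
    return np.flatnonzero(ok)


def scan_promoters(
    promoters: PromoterSet,
    motif: MotifPattern,
    strands: str = "both",
) -> tuple[list[MotifHit], set[str]]:
    """Find every degenerate match of the motif in every promoter.

    With ``strands="both"`` the reverse complement of the motif is also
    matched against the stored plus-strand sequence (a hit there is
    reported with strand "-").  Overlapping hits are all reported;
    ``positive_genes`` is the set of genes with at least one hit.
    """
    if strands not in ("both", "plus-only", "plus"):
        raise ValueError(f"strands must be 'both' or 'plus-only', got {strands!r}")
    fwd = _match_table(motif)
    rev = _match_table(motif.reverse_complement) if strands == "both" else None
    hits: list[MotifHit] = []
    positive: set[str] = set()
    L = len(motif)
    for gene in sorted(promoters.sequences):
        seq = promoters.sequences[gene]
        for off in _scan_one(seq, fwd):
            hits.append(MotifHit(gene, int(off), "+", seq[off : off + L]))
        if rev is not None:
            for off in _scan_one(seq, rev):
                hits.append(MotifHit(gene, int(off), "-", seq[off : off + L]))
    positive = {h.gene for h in hits}
    return hits, positive


def fisher_exact_one_sided(t: ContingencyTable) -> tuple[float, float]:
    """One-sided Fisher's exact test for over-representation.

    p = P(X >= a) under the hypergeometric distribution with the table's
    margins fixed (computed in log space by scipy); the odds ratio is
    a*d / (b*c), infinite when b*c = 0 with a*d > 0.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n_total = a + b + c + d
    if (a + b) == 0:
        raise ValueError("the in-set row margin must be positive for a defined test")
    # degenerate margins elsewhere are fine: with an empty complement row
    # (or an all-positive/all-negative column) the upper tail spans the
    # whole support and p = 1
    p = float(stats.hypergeom.sf(a - 1, n_total, a + c, a + b))
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    return min(p, 1.0), odds


def motif_enrichment(
    promoters_all: PromoterSet,
    study_set: set[str],
    motif: MotifPattern,
    strands: str = "both",
) -> MotifEnrichmentResult:
    """Test a study set for motif-positive promoter over-representation.

    Rows of the table are the study set vs all remaining genes with
    retrievable promoters; columns are motif-positive vs motif-negative.
    """
    study = set(study_set)
    if not study:
        raise ValueError("study set is empty")
    missing = study - promoters_all.genes
    if missing:
        raise ValueError(
            f"{len(missing)} study genes lack promoters, e.g. {sorted(missing)[:3]}"
        )
    hits, positive = scan_promoters(promoters_all, motif, strands=strands)
    background = promoters_all.genes - study
    a = len(study & positive)
    b = len(study) - a
    c = len(background & positive)
    d = len(background) - c
    table = ContingencyTable(a, b, c, d)
    p, odds = fisher_exact_one_sided(table)
    return MotifEnrichmentResult(
        table=table,
        p_value=p,
        odds_ratio=odds,
        positives_in_set=a,
        hits=hits,
        positive_genes=positive,
    )
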