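"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the statistical structure of the HacA^CA vs
HacA^WT transcriptome study: 12 microarrays (3 biological replicates ×
4 conditions — wild type and three constitutive-activation timepoints),
planted differential expression with consistent effects across the CA
conditions, promoters with planted UPRE instances, a layered toy GO DAG
with one boosted term, and two-phase (exponential then linear) batch
culture curves.  Every generator is deterministic given its seed and
records its planted truth in a :class:`SimTruth`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

from .motif import MotifPattern
from .summarize import ExpressionMatrix, ProbeIntensityMatrix

__all__ = [
    "CONDITIONS",
    "SimTruth",
    "default_design",
    "generate_probe_data",
    "generate_expression_matrix",
    "generate_promoters",
    "generate_go_universe",
    "generate_culture",
]

CONDITIONS = ("WT", "CA1", "CA2", "CA3")

#: Probe-level log2 noise SD calibrated by Monte Carlo so that the
#: summarized replicate CV on the linear scale lands near the middle of
#: the study's 0.12-0.14 band with the default 11 probes per probeset.
DEFAULT_NOISE_SD_LOG2 = 0.62


@dataclass
class SimTruth:
    """Ground truth planted by the generators.

    de_genes maps gene -> {condition: true log2 effect vs WT}; genes not
    listed have zero effect everywhere.
    """

    de_genes: dict[str, dict[str, float]] = field(default_factory=dict)
    motif_genes: set[str] = field(default_factory=set)
    enriched_term: str | None = None
    kinetic_params: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["motif_genes"] = sorted(self.motif_genes)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            payload = json.load(fh)
        payload["motif_genes"] = set(payload.get("motif_genes", []))
        return cls(**payload)


def default_design(n_replicates: int = 3) -> pd.DataFrame:
    """3 replicates × 4 conditions = 12 arrays, the study's layout."""
    rows = [
        {"array_id": f"{cond}_r{r}", "condition": cond, "replicate": r}
        for cond in CONDITIONS
        for r in range(1, n_replicates + 1)
    ]
    return pd.DataFrame(rows)


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:04d}" for i in range(1, n + 1)]


def _validate_design(design: pd.DataFrame) -> None:
    missing = set(CONDITIONS) - set(design["condition"])
    if missing:
        raise ValueError(f"design lacks conditions {sorted(missing)}")
    dup = design.duplicated(subset=["condition", "replicate"])
    if dup.any():
        raise ValueError("replicate ids must be unique within condition")


def _plant_effects(
    rng: np.random.Generator, genes: list[str], de_fraction: float, effect: float
) -> dict[str, dict[str, float]]:
    n_de = int(round(len(genes) * de_fraction))
    chosen = rng.choice(len(genes), size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    return {
        genes[i]: {c: float(s * effect) for c in CONDITIONS if c != "WT"}
        for i, s in zip(sorted(chosen), signs)
    }


def generate_probe_data(
    design: pd.DataFrame,
    n_genes: int = 1000,
    probes_per_gene: int = 11,
    de_fraction: float = 0.1,
    effect_size_log2: float = 2.0,
    noise_sd_log2: float = DEFAULT_NOISE_SD_LOG2,
    seed: int = 0,
    affinity_sd: float = 0.5,
    background: tuple[float, float] | None = None,
) -> tuple[ProbeIntensityMatrix, SimTruth]:
    """Probe-level intensities under an additive log2 model.

    intensity = 2^(theta_gc + phi_p + eps) with gene/condition means
    theta_gc (baseline Uniform(6, 12) plus the planted log2 effect for
    DE genes in CA conditions), probe affinities phi_p drawn once per
    probe and zero-centred within each probeset, and i.i.d. Gaussian
    log2 noise eps.  ``background`` optionally adds a raw-scale
    Normal(mu, sd) offset (clipped to keep intensities positive) to
    exercise background correction; it is off by default.
    """
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    if probes_per_gene < 1:
        raise ValueError("probes_per_gene must be positive")
    if not 0 <= de_fraction <= 1:
        raise ValueError("de_fraction must lie in [0, 1]")
    if noise_sd_log2 < 0:
        raise ValueError("noise_sd_log2 must be non-negative")
    _validate_design(design)
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    n_arrays = len(design)
    baseline = rng.uniform(6.0, 12.0, size=n_genes)
    de_genes = _plant_effects(rng, genes, de_fraction, effect_size_log2)
    # gene x array matrix of true log2 means
    cond_of = design["condition"].tolist()
    theta = np.tile(baseline[:, None], (1, n_arrays))
    gene_index = {g: i for i, g in enumerate(genes)}
    for gene, effects in de_genes.items():
        for a, cond in enumerate(cond_of):
            theta[gene_index[gene], a] += effects.get(cond, 0.0)
    phi = rng.normal(0.0, affinity_sd, size=(n_genes, probes_per_gene))
    phi -= phi.mean(axis=1, keepdims=True)
    eps = rng.normal(0.0, noise_sd_log2, size=(n_genes, probes_per_gene, n_arrays))
    log2_intensity = theta[:, None, :] + phi[:, :, None] + eps
    intensity = np.exp2(log2_intensity)
    if background is not None:
        mu_bg, sd_bg = background
        offset = rng.normal(mu_bg, sd_bg, size=intensity.shape)
        intensity = np.maximum(intensity + offset, 1e-6)
    probe_ids = [
        f"{g}_p{p + 1:02d}" for g in genes for p in range(probes_per_gene)
    ]
    values = pd.DataFrame(
        intensity.reshape(n_genes * probes_per_gene, n_arrays),
        index=probe_ids,
        columns=design["array_id"].tolist(),
    )
    probe_map = pd.Series(
        [g for g in genes for _ in range(probes_per_gene)], index=probe_ids
    )
    truth = SimTruth(de_genes=de_genes)
    return ProbeIntensityMatrix(values, probe_map), truth


def generate_expression_matrix(
    design: pd.DataFrame,
    n_genes: int = 1000,
    n_de: int = 100,
    effect_size_log2: float = 2.0,
    noise_sd_log2: float = 0.3,
    de_sign: int | None = None,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SimTruth]:
    """Gene-level log2 expression directly (no probe layer).

    Convenience generator for testing the DE stage in isolation: each
    gene's replicate values are Normal(theta_gc, noise_sd_log2^2).
    ``de_sign`` forces all planted effects up (+1) or down (-1); None
    randomizes the sign per gene.
    """
    if n_de > n_genes:
        raise ValueError("n_de cannot exceed n_genes")
    _validate_design(design)
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    baseline = rng.uniform(6.0, 12.0, size=n_genes)
    chosen = sorted(rng.choice(n_genes, size=n_de, replace=False))
    signs = (
        rng.choice([-1.0, 1.0], size=n_de)
        if de_sign is None
        else np.full(n_de, float(de_sign))
    )
    de_genes = {
        genes[i]: {c: float(s * effect_size_log2) for c in CONDITIONS if c != "WT"}
        for i, s in zip(chosen, signs)
    }
    cond_of = design["condition"].tolist()
    theta = np.tile(baseline[:, None], (1, len(design)))
    gene_index = {g: i for i, g in enumerate(genes)}
    for gene, effects in de_genes.items():
        for a, cond in enumerate(cond_of):
            theta[gene_index[gene], a] += effects.get(cond, 0.0)
    values = theta + rng.normal(0.0, noise_sd_log2, size=theta.shape)
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=design["array_id"].tolist())
    )
    return expr, SimTruth(de_genes=de_genes)


def generate_promoters(
    n_genes: int = 500,
    length: int = 400,
    gc_content: float = 0.5,
    planted_genes: set[str] | None = None,
    motif: MotifPattern | None = None,
    seed: int = 0,
    gene_ids: list[str] | None = None,
) -> tuple["PromoterSet", SimTruth]:
    """Random promoters with exact motif instances planted in some genes.

    Background sequence is i.i.d. at the requested GC content.  Each
    planted gene receives one instance drawn uniformly from the motif's
    expansion (each degenerate position sampled uniformly from its
    allowed bases) at a uniform random position; chance background hits
    may of course also occur, in planted and unplanted genes alike.
    """
    from .motif import PromoterSet  # local import avoids a cycle at import time

    genes = gene_ids if gene_ids is not None else _gene_ids(n_genes)
    planted = set(planted_genes or ())
    unknown = planted - set(genes)
    if unknown:
        raise ValueError(f"planted genes outside universe: {sorted(unknown)[:3]}")
    if planted and motif is None:
        raise ValueError("a motif is required to plant instances")
    if motif is not None and len(motif) > length:
        raise ValueError("motif longer than promoter length")
    if not 0 < gc_content < 1:
        raise ValueError("gc_content must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    probs = np.array(
        [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
    )
    sequences: dict[str, str] = {}
    for gene in genes:
        seq = rng.choice(bases, size=length, p=probs)
        if gene in planted:
            word = [
                sorted(allowed)[rng.integers(len(allowed))] for allowed in motif.allowed
            ]
            pos = int(rng.integers(0, length - len(motif) + 1))
            seq[pos : pos + len(motif)] = word
        sequences[gene] = "".join(seq)
    return PromoterSet(sequences, window=length), SimTruth(motif_genes=planted)


def generate_go_universe(
    n_terms: int = 50,
    n_genes: int = 1000,
    annotations_per_gene: int = 3,
    enriched_term: str = "t0010",
    study_set: set[str] | None = None,
    enrichment_boost: float = 20.0,
    seed: int = 0,
    n_layers: int = 4,
    background_rate: float = 0.05,
) -> tuple[nx.DiGraph, dict[str, set[str]], SimTruth]:
    """A layered rooted GO-like DAG with one boosted term.

    Terms t0000 (the root) .. t{n-1} are placed on layers; each non-root
    term gets 1-2 parents from strictly shallower layers, so the graph
    is acyclic and every term reaches the single root.  Each gene draws
    ``annotations_per_gene`` direct annotations uniformly from non-root
    terms; the enriched term is then added with background probability
    ``background_rate``, boosted on the odds scale by
    ``enrichment_boost`` for study-set genes.  boost = 1 plants nothing.
    """
    if enrichment_boost < 1:
        raise ValueError("enrichment_boost must be >= 1")
    if n_terms < 3:
        raise ValueError("need at least 3 terms")
    terms = [f"t{i:04d}" for i in range(n_terms)]
    if enriched_term not in terms:
        raise ValueError(f"enriched term {enriched_term!r} not among the {n_terms} terms")
    rng = np.random.default_rng(seed)
    layer = np.zeros(n_terms, dtype=int)
    layer[1:] = rng.integers(1, n_layers + 1, size=n_terms - 1)
    # make sure layer 1 is populated so every parent chain terminates
    layer[1] = 1
    g = nx.DiGraph()
    g.add_nodes_from(terms)
    for i in range(1, n_terms):
        shallower = [j for j in range(n_terms) if layer[j] < layer[i]]
        k = min(int(rng.integers(1, 3)), len(shallower))
        parents = rng.choice(len(shallower), size=k, replace=False)
        for p in parents:
            g.add_edge(terms[i], terms[shallower[p]])
    genes = _gene_ids(n_genes)
    study = set(study_set or ())
    unknown = study - set(genes)
    if unknown:
        raise ValueError(f"study genes outside universe: {sorted(unknown)[:3]}")
    odds_bg = background_rate / (1 - background_rate)
    p_study = (enrichment_boost * odds_bg) / (1 + enrichment_boost * odds_bg)
    direct: dict[str, set[str]] = {}
    for gene in genes:
        ann = set(
            terms[j]
            for j in rng.choice(
                np.arange(1, n_terms), size=min(annotations_per_gene, n_terms - 1),
                replace=False,
            )
        )
        p_extra = p_study if (gene in study and enrichment_boost > 1) else background_rate
        if rng.random() < p_extra:
            ann.add(enriched_term)
        direct[gene] = ann
    truth = SimTruth(enriched_term=enriched_term if enrichment_boost > 1 else None)
    return g, direct, truth


def generate_culture(
    mu: float = 0.22,
    x0: float = 0.02,
    t_break: float | None = 21.0,
    linear_rate: float = 0.25,
    yield_xs: float = 0.53,
    s0: float = 7.5,
    alkali_per_biomass: float = 0.008,
    noise_cv: float = 0.0,
    sample_times: np.ndarray | None = None,
    seed: int = 0,
) -> tuple["CultureTimeSeries", SimTruth]:
    """Two-phase batch culture: exponential to t_break, then linear.

    Biomass follows x0·e^(μt) up to ``t_break`` and continues linearly
    (slope ``linear_rate``) afterwards, continuous at the break;
    ``t_break=None`` keeps growth exponential throughout.  Glucose obeys
    the mass balance S = s0 − (X − x0)/Y_xs floored at zero, and
    cumulative alkali is proportional to biomass formed.  Multiplicative
    mean-one lognormal noise at the stated CV is applied per observation
    (to alkali *increments*, keeping the cumulative trace monotone).
    """
    for name, v in [("mu", mu), ("x0", x0), ("linear_rate", linear_rate),
                    ("yield_xs", yield_xs), ("s0", s0),
                    ("alkali_per_biomass", alkali_per_biomass)]:
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    from .kinetics import CultureTimeSeries  # avoid import cycle

    t = (
        np.asarray(sample_times, dtype=float)
        if sample_times is not None
        else np.arange(1.0, 31.0, 1.0)
    )
    if t_break is None:
        x = x0 * np.exp(mu * t)
    else:
        x_break = x0 * np.exp(mu * t_break)
        x = np.where(
            t <= t_break,
            x0 * np.exp(mu * t),
            x_break + linear_rate * (t - t_break),
        )
    glucose = np.maximum(s0 - (x - x0) / yield_xs, 0.0)
    alkali = alkali_per_biomass * (x - x0)
    rng = np.random.default_rng(seed)
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))

        def factor(n):
            return np.exp(rng.normal(0.0, sigma, size=n) - sigma**2 / 2)

        x = x * factor(len(t))
        glucose = glucose * factor(len(t))
        increments = np.diff(np.concatenate(([0.0], alkali)))
        alkali = np.cumsum(increments * factor(len(t)))
    data = pd.DataFrame(
        {
            "time_h": t,
            "biomass_gdw_kg": x,
            "alkali_cum_mol": alkali,
            "glucose_g_l": glucose,
        }
    )
    truth = SimTruth(
        kinetic_params={
            "mu": mu,
            "t_break": float("nan") if t_break is None else t_break,
            "linear_rate": linear_rate,
            "yield": yield_xs,
        }
    )
    return CultureTimeSeries(data), truth
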