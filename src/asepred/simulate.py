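"""Synthetic cohorts with known ground truth.

Emulates the data a cohort ASE study works from: per-individual allelic
read counts at heterozygous loci (beta-binomially distributed
alternative-allele fractions, null loci centred at 0.5, ASE loci
shifted, shared overdispersion), a read-depth distribution, and a
variant annotation matrix whose columns carry planted monotone signal
for the ASE label plus missing values and categorical columns.  Every
generator is reproducible from its seed; per-locus substreams are keyed
by locus index so any subset of loci is reproducible independent of
iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureMatrix, FeatureSpec


class ConfigError(ValueError):
    """A simulation configuration field is invalid; the message names it."""


def _locus_rng(seed: int, index: int) -> np.random.Generator:
    # counter-based substream: one child stream per locus index
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def _validate_depth_spec(spec: dict) -> None:
    kind = spec.get("kind")
    if kind == "fixed":
        if int(spec.get("value", 0)) < 1:
            raise ConfigError("depth_distribution.value must be >= 1")
    elif kind == "negative_binomial":
        if spec.get("mean", 0) <= 1:
            raise ConfigError("depth_distribution.mean must exceed 1")
        if spec.get("dispersion", 0) <= 0:
            raise ConfigError("depth_distribution.dispersion must be positive")
    else:
        raise ConfigError(f"depth_distribution.kind {kind!r} not recognised")


def _draw_depths(spec: dict, size: int, rng: np.random.Generator) -> np.ndarray:
    if spec["kind"] == "fixed":
        return np.full(size, int(spec["value"]), dtype=int)
    # shifted negative binomial: 1 + NB with mean (mean - 1), so depth >= 1
    r = float(spec["dispersion"])
    mu = float(spec["mean"]) - 1.0
    p = r / (r + mu)
    return 1 + rng.negative_binomial(r, p, size=size)


def _validate_pi_ase_spec(spec: dict) -> None:
    kind = spec.get("kind")
    if kind == "fixed":
        v = spec.get("value")
        if v is None or not (0.0 < v < 1.0) or v == 0.5:
            raise ConfigError("pi_ase_distribution.value must be in (0,1) and differ from 0.5")
    elif kind == "mirrored_uniform":
        lo, hi = spec.get("low"), spec.get("high")
        if lo is None or hi is None or not (0.5 < lo < hi < 1.0):
            raise ConfigError("pi_ase_distribution requires 0.5 < low < high < 1")
    else:
        raise ConfigError(f"pi_ase_distribution.kind {kind!r} not recognised")


def _draw_pi_ase(spec: dict, rng: np.random.Generator) -> float:
    if spec["kind"] == "fixed":
        return float(spec["value"])
    u = rng.uniform(spec["low"], spec["high"])
    # mirror to the under-expressed side with probability 1/2
    return float(1.0 - u) if rng.random() < 0.5 else float(u)


@dataclass
class CohortSimConfig:
    """Settings for one simulated allelic-count cohort.

    ``n_individuals_per_locus`` is either a fixed integer or an
    inclusive ``(low, high)`` range; ``rho`` is the overdispersion shared
    by all loci; ``ase_fraction`` of loci draw their mean alternative
    fraction from ``pi_ase_distribution`` instead of ``pi_null``.
    """

    n_loci: int = 200
    n_individuals_per_locus: int | tuple[int, int] = 30
    depth_distribution: dict = field(
        default_factory=lambda: {"kind": "negative_binomial", "mean": 40, "dispersion": 5})
    ase_fraction: float = 0.15
    pi_null: float = 0.5
    pi_ase_distribution: dict = field(
        default_factory=lambda: {"kind": "mirrored_uniform", "low": 0.6, "high": 0.95})
    rho: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_loci < 1:
            raise ConfigError("n_loci must be positive")
        ind = self.n_individuals_per_locus
        if isinstance(ind, (tuple, list)):
            if len(ind) != 2 or ind[0] < 1 or ind[1] < ind[0]:
                raise ConfigError("n_individuals_per_locus range must satisfy 1 <= low <= high")
        elif int(ind) < 1:
            raise ConfigError("n_individuals_per_locus must be >= 1")
        if not (0.0 <= self.ase_fraction <= 1.0):
            raise ConfigError("ase_fraction must lie in [0, 1]")
        if not (0.0 < self.pi_null < 1.0):
            raise ConfigError("pi_null must lie strictly inside (0, 1)")
        if not (0.0 < self.rho < 1.0):
            raise ConfigError("rho must lie strictly inside (0, 1)")
        _validate_depth_spec(self.depth_distribution)
        _validate_pi_ase_spec(self.pi_ase_distribution)


@dataclass
class SimulatedCohort:
    counts: pd.DataFrame        # locus_id, individual_id, ref_count, alt_count
    truth: pd.DataFrame         # locus_id, is_ase, true_pi
    config: CohortSimConfig

    def write(self, counts_path, truth_path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index=False)
        self.truth.to_csv(truth_path, sep="\t", index=False)


_BASES = np.array(["A", "C", "G", "T"])


def simulate_cohort(config: CohortSimConfig) -> SimulatedCohort:
    """Draw a cohort of heterozygous loci with beta-binomial allelic counts."""
    from .betabin import sample_betabin

    rows = []
    truth_rows = []
    for i in range(config.n_loci):
        rng = _locus_rng(config.seed, i)
        ref, alt = rng.choice(4, size=2, replace=False)
        locus_id = f"chr{1 + i % 22}:{1000 + 10 * i}:{_BASES[ref]}:{_BASES[alt]}"
        is_ase = bool(rng.random() < config.ase_fraction)
        pi = _draw_pi_ase(config.pi_ase_distribution, rng) if is_ase else config.pi_null
        ind = config.n_individuals_per_locus
        m = (int(rng.integers(ind[0], ind[1] + 1))
             if isinstance(ind, (tuple, list)) else int(ind))
        depths = _draw_depths(config.depth_distribution, m, rng)
        alts = sample_betabin(depths, pi, config.rho, rng)
        for j in range(m):
            rows.append((locus_id, f"ind{j:04d}", int(depths[j] - alts[j]), int(alts[j])))
        truth_rows.append((locus_id, is_ase, pi))

    counts = pd.DataFrame(rows, columns=["locus_id", "individual_id", "ref_count", "alt_count"])
    truth = pd.DataFrame(truth_rows, columns=["locus_id", "is_ase", "true_pi"])
    return SimulatedCohort(counts=counts, truth=truth, config=config)


@dataclass
class FeatureSimConfig:
    """Settings for a planted-signal annotation matrix.

    ``effect_vector`` gives one coefficient per feature (numeric first,
    then categorical): numeric features are shifted by ``effect * label``
    on a unit-variance base, categorical features tilt their category
    frequencies for labelled rows.  Missing entries are inserted
    independently at ``missing_rate``.
    """

    n_features_numeric: int = 10
    n_features_categorical: int = 2
    effect_vector: tuple | None = None
    missing_rate: float = 0.0
    n_categories: int = 3
    seed: int = 0

    def __post_init__(self):
        n = self.n_features_numeric + self.n_features_categorical
        if n < 1:
            raise ConfigError("at least one feature is required")
        if self.effect_vector is not None and len(self.effect_vector) != n:
            raise ConfigError(
                f"effect_vector length {len(self.effect_vector)} != n_features {n}")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must lie in [0, 1)")
        if self.n_categories < 2:
            raise ConfigError("n_categories must be >= 2")


def simulate_feature_matrix(truth: pd.Series, config: FeatureSimConfig) -> FeatureMatrix:
    """Generate an annotation matrix carrying planted signal for ``truth``.

    ``truth`` is a boolean/binary series indexed by locus id.  The
    returned matrix keeps the true effects on ``matrix.sim_effects`` for
    recovery tests.
    """
    if len(truth) == 0:
        raise ConfigError("truth labels must be nonempty")
    y = truth.astype(int).to_numpy()
    n = len(y)
    n_num, n_cat = config.n_features_numeric, config.n_features_categorical
    effects = (np.zeros(n_num + n_cat) if config.effect_vector is None
               else np.asarray(config.effect_vector, dtype=float))
    rng = np.random.default_rng(config.seed)

    cols, specs, sim_effects = {}, [], {}
    cats = [chr(ord("A") + i) for i in range(config.n_categories)]
    for j in range(n_num):
        name = f"num_{j:02d}"
        cols[name] = rng.normal(0.0, 1.0, size=n) + effects[j] * y
        specs.append(FeatureSpec(name, "numeric"))
        sim_effects[name] = float(effects[j])
    pos = np.arange(config.n_categories) / max(1, config.n_categories - 1)
    for j in range(n_cat):
        name = f"cat_{j:02d}"
        e = effects[n_num + j]
        base = np.full(config.n_categories, 1.0 / config.n_categories)
        tilt = np.exp(e * pos)
        tilt = tilt / tilt.sum()
        draws = np.empty(n, dtype=object)
        for label, p in ((0, base), (1, tilt)):
            idx = np.flatnonzero(y == label)
            if idx.size:
                draws[idx] = rng.choice(cats, size=idx.size, p=p)
        cols[name] = pd.Series(draws, dtype="object")
        specs.append(FeatureSpec(name, "categorical"))
        sim_effects[name] = float(e)

    values = pd.DataFrame(cols)
    values.index = pd.Index(truth.index, name="locus_id")
    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        values = values.mask(pd.DataFrame(mask, index=values.index, columns=values.columns))
    matrix = FeatureMatrix(values, specs)
    matrix.sim_effects = sim_effects
    return matrix


@dataclass
class GeneSetSim:
    gene_sets: dict[str, list[str]]   # term id -> member genes
    universe: list[str]
    enriched_term: str | None = None
    enriched_subset: list[str] | None = None


def simulate_gene_annotation(n_genes: int, n_terms: int,
                             genes_per_term: tuple[int, int] = (5, 20),
                             seed: int = 0,
                             enriched_subset_size: int = 0) -> GeneSetSim:
    """Random gene-set collection over a synthetic gene universe.

    With ``enriched_subset_size > 0`` one designated gene subset and one
    term drawn almost entirely from it are planted as a positive control
    for over-representation ranking.
    """
    lo, hi = genes_per_term
    if not (1 <= lo <= hi):
        raise ConfigError("genes_per_term must satisfy 1 <= low <= high")
    if n_genes < hi:
        raise ConfigError(f"n_genes={n_genes} smaller than max genes_per_term={hi}")
    if enriched_subset_size and enriched_subset_size > n_genes:
        raise ConfigError("enriched_subset_size exceeds n_genes")
    rng = np.random.default_rng(seed)
    universe = [f"GENE{i:05d}" for i in range(n_genes)]
    gene_sets = {}
    for t in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(n_genes, size=size, replace=False)
        gene_sets[f"TERM{t:04d}"] = sorted(universe[g] for g in members)

    enriched_term = enriched_subset = None
    if enriched_subset_size > 0:
        if n_terms == 0:
            raise ConfigError("cannot plant an enriched term with n_terms=0")
        subset_idx = rng.choice(n_genes, size=enriched_subset_size, replace=False)
        enriched_subset = sorted(universe[g] for g in subset_idx)
        size = min(hi, enriched_subset_size)
        members = rng.choice(enriched_subset, size=size, replace=False)
        enriched_term = "TERM_PLANTED"
        gene_sets[enriched_term] = sorted(members)
    return GeneSetSim(gene_sets=gene_sets, universe=universe,
                      enriched_term=enriched_term, enriched_subset=enriched_subset)
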