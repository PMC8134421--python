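"""Cohort-level ASE calling.

Each heterozygous locus is tested for allele-specific expression by
aggregating every individual's allelic read counts under a beta-binomial
model.  The null model fixes the mean alternative-allele fraction at 0.5
(overdispersion free); the alternative model frees both parameters.  The
likelihood-ratio statistic ``2 * (LL_alt - LL_null)`` is referred to a
chi-square distribution with one degree of freedom, and loci are flagged
as ASE when their Benjamini-Hochberg q-value falls below the FDR
threshold.  Following common cohort practice, only loci observed in at
least ``min_individuals`` individuals (default 5) are tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .betabin import BetaBinFit, fit_locus

logger = logging.getLogger(__name__)

COUNT_COLUMNS = ["locus_id", "individual_id", "ref_count", "alt_count"]


def read_count_table(path) -> pd.DataFrame:
    """Read a tab-separated allelic count table.

    Expected header: ``locus_id  individual_id  ref_count  alt_count``
    with locus ids of the form ``chr:pos:ref:alt`` (1-based positions).
    """
    df = pd.read_csv(path, sep="\t", dtype={"locus_id": str, "individual_id": str})
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"count table missing column(s): {missing}")
    return df[COUNT_COLUMNS]


def _validate_counts(df: pd.DataFrame) -> pd.DataFrame:
    if df.empty:
        raise ValueError("count table is empty")
    if (df["ref_count"] < 0).any() or (df["alt_count"] < 0).any():
        raise ValueError("negative read counts in table")
    dup = df.duplicated(subset=["locus_id", "individual_id"])
    if dup.any():
        raise ValueError(
            f"duplicate (locus, individual) pairs: {df.loc[dup, 'locus_id'].unique()[:5].tolist()}")
    zero = df["ref_count"] + df["alt_count"] == 0
    if zero.any():
        logger.info("dropping %d records with zero total reads", int(zero.sum()))
        df = df.loc[~zero]
    return df


@dataclass
class AseCallResult:
    """Per-locus ASE test outcome."""

    locus_id: str
    null_fit: BetaBinFit
    alt_fit: BetaBinFit
    lrt_stat: float
    p_value: float
    q_value: float
    is_ase: bool
    n_individuals: int


def lrt_test(counts, null_pi: float = 0.5) -> tuple[float, float]:
    """Likelihood-ratio test of balanced expression at one locus.

    Returns ``(lrt_stat, p_value)``; the statistic is clipped at zero
    because the bounded optimizers can leave the alternative fit
    marginally below the null.  ``p_value`` is nan when either fit failed
    to converge.
    """
    null_fit = fit_locus(counts, fix_pi=null_pi)
    alt_fit = fit_locus(counts)
    stat = max(0.0, 2.0 * (alt_fit.loglik - null_fit.loglik))
    if null_fit.converged and alt_fit.converged:
        p = float(chi2.sf(stat, df=1))
    else:
        p = float("nan")
    return stat, p


class AseCohortModel:
    """Beta-binomial ASE model for a cohort allelic count table.

    Parameters
    ----------
    counts : pandas.DataFrame
        Long-format table with columns ``locus_id, individual_id,
        ref_count, alt_count``.  Records with zero total reads are
        dropped (logged); duplicate (locus, individual) pairs are an
        error.
    null_pi : float
        Mean alternative-allele fraction under the null (0.5 = balanced).

    Examples
    --------
    >>> results = AseCohortModel(counts).fit(min_individuals=5, fdr_threshold=0.05)
    >>> results.table.head()
    """

    def __init__(self, counts: pd.DataFrame, null_pi: float = 0.5):
        self.counts = _validate_counts(counts.copy())
        self.null_pi = float(null_pi)

    @classmethod
    def from_table(cls, path, **kwargs) -> "AseCohortModel":
        return cls(read_count_table(path), **kwargs)

    def fit(self, min_individuals: int = 5, fdr_threshold: float = 0.05) -> "AseCohortResults":
        """Test every locus and control FDR across the cohort."""
        sizes = self.counts.groupby("locus_id").size()
        kept = sizes.index[sizes >= min_individuals]
        n_dropped = len(sizes) - len(kept)
        if n_dropped:
            logger.info("excluded %d loci observed in fewer than %d individuals",
                        n_dropped, min_individuals)
        if len(kept) == 0:
            logger.warning("no locus passes the %d-individual filter; empty result",
                           min_individuals)
            return AseCohortResults([], self, min_individuals, fdr_threshold)

        results = []
        grouped = self.counts[self.counts["locus_id"].isin(kept)].groupby("locus_id")
        for locus_id, grp in grouped:
            pairs = list(zip(grp["alt_count"].to_numpy(),
                             (grp["ref_count"] + grp["alt_count"]).to_numpy()))
            null_fit = fit_locus(pairs, fix_pi=self.null_pi)
            alt_fit = fit_locus(pairs)
            stat = max(0.0, 2.0 * (alt_fit.loglik - null_fit.loglik))
            if null_fit.converged and alt_fit.converged:
                p = float(chi2.sf(stat, df=1))
            else:
                p = float("nan")
            results.append(AseCallResult(
                locus_id=locus_id, null_fit=null_fit, alt_fit=alt_fit,
                lrt_stat=stat, p_value=p, q_value=float("nan"),
                is_ase=False, n_individuals=len(pairs)))

        tested = [r for r in results if np.isfinite(r.p_value)]
        if len(tested) < len(results):
            logger.warning("%d loci excluded from FDR due to non-convergence",
                           len(results) - len(tested))
        if tested:
            pvals = np.array([r.p_value for r in tested])
            _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
            for r, q in zip(tested, qvals):
                r.q_value = float(q)
                r.is_ase = bool(q < fdr_threshold)
        results.sort(key=lambda r: (r.p_value if np.isfinite(r.p_value) else np.inf,
                                    r.locus_id))
        return AseCohortResults(results, self, min_individuals, fdr_threshold)


class AseCohortResults:
    """Fitted ASE calls for a cohort; iterable list plus a tidy table."""

    def __init__(self, results: list[AseCallResult], model: AseCohortModel,
                 min_individuals: int, fdr_threshold: float):
        self.results = results
        self.model = model
        self.min_individuals = min_individuals
        self.fdr_threshold = fdr_threshold

    def __len__(self):
        return len(self.results)

    def __iter__(self):
        return iter(self.results)

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "locus_id": [r.locus_id for r in self.results],
            "n_individuals": [r.n_individuals for r in self.results],
            "pi_hat": [r.alt_fit.pi_hat for r in self.results],
            "rho_hat": [r.alt_fit.rho_hat for r in self.results],
            "lrt_stat": [r.lrt_stat for r in self.results],
            "p_value": [r.p_value for r in self.results],
            "q_value": [r.q_value for r in self.results],
            "is_ase": [r.is_ase for r in self.results],
        })

    @property
    def ase_loci(self) -> list[str]:
        return [r.locus_id for r in self.results if r.is_ase]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        n = len(self.results)
        n_ase = sum(r.is_ase for r in self.results)
        lines = [
            "ASE cohort calling summary",
            "==========================",
            f"loci tested (>= {self.min_individuals} individuals): {n}",
            f"ASE loci at FDR < {self.fdr_threshold}: {n_ase}",
        ]
        if n:
            pi = np.array([r.alt_fit.pi_hat for r in self.results])
            lines.append(f"median |pi_hat - 0.5|: {np.median(np.abs(pi - 0.5)):.4f}")
        return "\n".join(lines)


def call_ase(table: pd.DataFrame, min_individuals: int = 5,
             fdr_threshold: float = 0.05) -> list[AseCallResult]:
    """Functional wrapper: fit the cohort model and return per-locus calls."""
    return AseCohortModel(table).fit(min_individuals, fdr_threshold).results
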