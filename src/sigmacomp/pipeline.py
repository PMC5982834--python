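"""Count-based regulon analysis: filtering, DE calling, shift statistics.

Implements the analysis definitions used on the strain x growth-phase
RNA-seq design (five strains, five growth phases, two replicates):

* a low-count filter — genes with <= ``threshold`` reads in every sample
  are excluded from all downstream statistics;
* differential-expression calling per (mutant, phase) contrast against
  wild-type: median-of-ratios normalization, log2 fold change of
  normalized means with a pseudocount, a negative-binomial Wald test with
  a single dispersion pooled across genes (two replicates cannot support
  gene-wise dispersion), Benjamini-Hochberg adjustment over filtered
  genes; DE means |log2fc| >= 1 and adjusted p < 0.05;
* regulon-shift statistics: two-sided Wilcoxon rank-sum of a gene set's
  log2 fold changes against all other filtered genes, with medians and
  the fraction of the set below zero;
* non-additivity: genes DE in the double knockout whose summed
  single-knockout log2 fold changes stay below the twofold line;
* dose dependence: genes whose fold change keeps one sign and strictly
  grows in magnitude across successive growth phases, DE by the final
  phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

STRAINS = ("WT", "rsd", "ssrS", "double", "rpoS")
PHASES = ("EE", "ME", "TS", "S", "LS")

DEFAULT_COUNT_THRESHOLD = 10
DEFAULT_LFC_THRESHOLD = 1.0  # log2 units, i.e. twofold
DEFAULT_ALPHA = 0.05
PSEUDOCOUNT = 0.5

__all__ = [
    "CountExperiment",
    "DEResult",
    "ShiftResult",
    "low_count_filter",
    "size_factors",
    "estimate_dispersion",
    "call_de",
    "regulon_shift",
    "non_additive_genes",
    "dose_dependent_genes",
    "STRAINS",
    "PHASES",
]


@dataclass
class CountExperiment:
    """Gene x sample counts with strain/phase/replicate metadata.

    ``counts``: genes in rows, samples in columns, nonnegative integers.
    ``samples``: indexed by sample id with columns ``strain``, ``phase``,
    ``replicate``. ``gene_sets`` maps a set name to a list of gene ids.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    gene_sets: dict[str, list[str]] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.size == 0:
            raise ValueError("empty count matrix")
        if self.counts.index.duplicated().any():
            raise ValueError("gene ids must be unique")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples missing metadata: {sorted(missing)}")
        for col in ("strain", "phase", "replicate"):
            if col not in self.samples.columns:
                raise ValueError(f"sample sheet lacks column {col!r}")
            if self.samples.loc[list(self.counts.columns), col].isna().any():
                raise ValueError(f"sample sheet column {col!r} has missing values")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be nonnegative")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integral")

    def sample_ids(self, strain: str, phase: str) -> list[str]:
        meta = self.samples.loc[list(self.counts.columns)]
        sel = meta[(meta["strain"] == strain) & (meta["phase"] == phase)]
        return list(sel.index)

    # -- text I/O ---------------------------------------------------------

    def write(self, outdir: str | Path, prefix: str = "experiment") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.counts.to_csv(outdir / f"{prefix}_counts.tsv", sep="\t", index_label="gene")
        self.samples.to_csv(outdir / f"{prefix}_samples.tsv", sep="\t", index_label="sample")
        rows = [(name, g) for name, genes in self.gene_sets.items() for g in genes]
        pd.DataFrame(rows, columns=["set", "gene"]).to_csv(
            outdir / f"{prefix}_gene_sets.tsv", sep="\t", index=False
        )

    @classmethod
    def read(
        cls,
        counts_path: str | Path,
        samples_path: str | Path,
        gene_sets_path: str | Path | None = None,
    ) -> "CountExperiment":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        samples = pd.read_csv(samples_path, sep="\t", index_col=0)
        gene_sets: dict[str, list[str]] = {}
        if gene_sets_path is not None:
            gs = pd.read_csv(gene_sets_path, sep="\t")
            for name, grp in gs.groupby("set"):
                gene_sets[str(name)] = list(grp["gene"].astype(str))
        return cls(counts=counts, samples=samples, gene_sets=gene_sets)


@dataclass(frozen=True)
class DEResult:
    """Per-gene differential expression for one (mutant, phase) contrast.

    ``table`` columns: ``log2fc`` (mutant minus wild-type on the log2
    scale), ``pvalue``, ``padj``, ``is_de``, ``passed_filter``. p-values
    and padj are NaN for genes failing the low-count filter.
    """

    mutant: str
    phase: str
    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def filtered(self) -> pd.DataFrame:
        return self.table[self.table["passed_filter"]]


@dataclass(frozen=True)
class ShiftResult:
    """Fold-change shift of one gene set against the filtered background."""

    set_name: str
    mutant: str
    phase: str
    n_set: int
    n_background: int
    median_log2fc_set: float
    median_log2fc_background: float
    fraction_below_zero_set: float
    ranksum_p: float

    def as_record(self) -> dict:
        return dict(self.__dict__)


def low_count_filter(
    expt: CountExperiment, threshold: int = DEFAULT_COUNT_THRESHOLD
) -> pd.Series:
    """Boolean mask per gene: True iff any sample exceeds ``threshold`` reads."""
    if expt.counts.size == 0:
        raise ValueError("empty count matrix")
    return expt.counts.max(axis=1) > threshold


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample.

    The reference is the per-gene geometric mean across samples, computed
    over genes with all-positive counts; each sample's factor is the
    median ratio of its counts to the reference.
    """
    positive = counts[(counts > 0).all(axis=1)]
    if positive.empty:
        raise ValueError("no gene has positive counts in every sample")
    logref = np.log(positive).mean(axis=1)
    sf = np.exp(np.log(positive).sub(logref, axis=0).median(axis=0))
    zero = sf[sf <= 0]
    if len(zero):
        raise ValueError(f"zero size factor for sample(s) {list(zero.index)}")
    return sf


def estimate_dispersion(
    expt: CountExperiment, sf: pd.Series | None = None, min_mean: float = 5.0
) -> float:
    """Single negative-binomial dispersion pooled across genes and groups.

    Method of moments on normalized counts: within each (strain, phase)
    group with >= 2 replicates, Var(K/s) ~= mu * mean(1/s) + alpha * mu^2.
    The excess variances are pooled by a regression-through-origin of
    (sample variance - Poisson part) on squared means, which is robust to
    the per-gene noise of two-replicate variance estimates.
    """
    if sf is None:
        sf = size_factors(expt.counts)
    num = 0.0
    den = 0.0
    meta = expt.samples.loc[list(expt.counts.columns)]
    for (_, _), grp in meta.groupby(["strain", "phase"], sort=True):
        ids = list(grp.index)
        if len(ids) < 2:
            continue
        q = expt.counts[ids].to_numpy(dtype=float) / sf[ids].to_numpy()
        m = q.mean(axis=1)
        v = q.var(axis=1, ddof=1)
        c1 = float(np.mean(1.0 / sf[ids].to_numpy()))
        keep = m >= min_mean
        num += float(np.sum(v[keep] - m[keep] * c1))
        den += float(np.sum(m[keep] ** 2))
    if den == 0.0:
        raise ValueError("no group with >= 2 replicates and sufficient counts")
    return max(num / den, 1e-8)


def _group_stats(
    counts: pd.DataFrame, ids: Sequence[str], sf: pd.Series, alpha_disp: float
) -> tuple[np.ndarray, np.ndarray]:
    """Mean of normalized counts and variance of that mean, per gene."""
    s = sf[list(ids)].to_numpy()
    q = counts[list(ids)].to_numpy(dtype=float) / s
    m = q.mean(axis=1)
    n = len(ids)
    # Var(K_j/s_j) = mu/s_j + alpha*mu^2 under NB(mu*s_j, alpha)
    mu = m + PSEUDOCOUNT  # stabilized at zero counts
    var_mean = (mu * np.mean(1.0 / s) + alpha_disp * mu**2) / n
    return m, var_mean


def call_de(
    expt: CountExperiment,
    mutant: str,
    phase: str,
    *,
    reference: str = "WT",
    count_threshold: int = DEFAULT_COUNT_THRESHOLD,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    dispersion: float | None = None,
) -> DEResult:
    """Differential expression of ``mutant`` vs wild-type in one phase.

    Normalization and the pooled dispersion use the whole experiment; the
    Wald test compares the two groups of the contrast on the log scale.
    """
    mut_ids = expt.sample_ids(mutant, phase)
    ref_ids = expt.sample_ids(reference, phase)
    if not mut_ids or not ref_ids:
        raise ValueError(
            f"no samples for contrast {mutant!r} vs {reference!r} in phase {phase!r}"
        )
    sf = size_factors(expt.counts)
    if dispersion is None:
        dispersion = estimate_dispersion(expt, sf)
    passed = low_count_filter(expt, count_threshold)

    m_mut, v_mut = _group_stats(expt.counts, mut_ids, sf, dispersion)
    m_ref, v_ref = _group_stats(expt.counts, ref_ids, sf, dispersion)
    log2fc = np.log2((m_mut + PSEUDOCOUNT) / (m_ref + PSEUDOCOUNT))
    # delta method on the log scale
    se = np.sqrt(
        v_mut / (m_mut + PSEUDOCOUNT) ** 2 + v_ref / (m_ref + PSEUDOCOUNT) ** 2
    )
    z = np.where(se > 0, np.log((m_mut + PSEUDOCOUNT) / (m_ref + PSEUDOCOUNT)) / se, 0.0)
    pvalue = 2.0 * stats.norm.sf(np.abs(z))

    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": pvalue,
            "padj": np.nan,
            "is_de": False,
            "passed_filter": passed.to_numpy(),
        },
        index=expt.counts.index,
    )
    mask = table["passed_filter"].to_numpy()
    if mask.any():
        padj = multipletests(table.loc[mask, "pvalue"], method="fdr_bh")[1]
        table.loc[mask, "padj"] = padj
        table.loc[mask, "is_de"] = (
            (table.loc[mask, "log2fc"].abs() >= lfc_threshold) & (padj < alpha)
        ).to_numpy()
    table.loc[~mask, "pvalue"] = np.nan
    meta = {
        "mutant": mutant,
        "reference": reference,
        "phase": phase,
        "n_mutant": len(mut_ids),
        "n_reference": len(ref_ids),
        "dispersion": dispersion,
        "count_threshold": count_threshold,
        "lfc_threshold": lfc_threshold,
        "alpha": alpha,
        "test": "NB Wald, pooled method-of-moments dispersion",
        "normalization": "median-of-ratios",
    }
    return DEResult(mutant=mutant, phase=phase, table=table, metadata=meta)


def regulon_shift(
    de: DEResult, gene_set: Sequence[str], set_name: str = "gene_set"
) -> ShiftResult:
    """Rank-sum shift of a gene set's fold changes against all other genes."""
    filtered = de.filtered()
    genes = set(map(str, gene_set))
    unknown = genes - set(map(str, de.genes))
    if unknown:
        raise KeyError(f"gene set contains unknown gene(s), e.g. {sorted(unknown)[:5]}")
    in_set = filtered.index.astype(str).isin(genes)
    set_lfc = filtered.loc[in_set, "log2fc"].to_numpy()
    bg_lfc = filtered.loc[~in_set, "log2fc"].to_numpy()
    if set_lfc.size == 0:
        raise ValueError(f"gene set {set_name!r} is empty after filtering")
    if bg_lfc.size == 0:
        raise ValueError(f"background is empty: gene set {set_name!r} covers all filtered genes")
    stat = stats.mannwhitneyu(set_lfc, bg_lfc, alternative="two-sided")
    return ShiftResult(
        set_name=set_name,
        mutant=de.mutant,
        phase=de.phase,
        n_set=int(set_lfc.size),
        n_background=int(bg_lfc.size),
        median_log2fc_set=float(np.median(set_lfc)),
        median_log2fc_background=float(np.median(bg_lfc)),
        fraction_below_zero_set=float(np.mean(set_lfc < 0)),
        ranksum_p=float(stat.pvalue),
    )


def _check_same_universe(*des: DEResult) -> None:
    first = des[0]
    for other in des[1:]:
        if not first.genes.equals(other.genes):
            raise ValueError("DE results do not share the same gene universe")
        if other.phase != first.phase:
            raise ValueError(
                f"DE results span different phases: {first.phase!r} vs {other.phase!r}"
            )


def non_additive_genes(
    de_rsd: DEResult,
    de_ssrS: DEResult,
    de_double: DEResult,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
) -> list[str]:
    """Genes DE in the double knockout but additively below the twofold line.

    Selected: ``is_de`` in the double knockout and
    ``|log2fc_rsd + log2fc_ssrS| < lfc_threshold``.
    """
    _check_same_universe(de_rsd, de_ssrS, de_double)
    summed = de_rsd.table["log2fc"] + de_ssrS.table["log2fc"]
    sel = de_double.table["is_de"] & (summed.abs() < lfc_threshold)
    return list(de_double.genes[sel])


def dose_dependent_genes(
    de_by_phase: Sequence[DEResult],
    *,
    require_final_de: bool = True,
    require_strict_increase: bool = True,
) -> list[str]:
    """Genes with a one-signed, monotonically growing fold change across phases.

    ``de_by_phase`` must be ordered by growth phase (EE first). A gene is
    selected when it passes the filter in every phase, its log2 fold
    change keeps one strict sign throughout, its magnitude strictly
    increases phase over phase (set ``require_strict_increase=False`` for
    the non-strict variant), and — by default — it is DE in the final
    phase.
    """
    if len(de_by_phase) < 2:
        raise ValueError("need DE results for at least two phases")
    first = de_by_phase[0]
    for other in de_by_phase[1:]:
        if not first.genes.equals(other.genes):
            raise ValueError("DE results do not share the same gene universe")
    lfc = np.column_stack([de.table["log2fc"].to_numpy() for de in de_by_phase])
    passed = np.column_stack([de.table["passed_filter"].to_numpy() for de in de_by_phase]).all(axis=1)
    one_sign = (lfc > 0).all(axis=1) | (lfc < 0).all(axis=1)
    diffs = np.diff(np.abs(lfc), axis=1)
    growing = (diffs > 0).all(axis=1) if require_strict_increase else (diffs >= 0).all(axis=1)
    sel = passed & one_sign & growing
    if require_final_de:
        sel &= de_by_phase[-1].table["is_de"].to_numpy()
    return list(first.genes[sel])
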