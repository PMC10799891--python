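"""Fold-change imbalance and related cross-class statistics.

The imbalance of an RNA class is the fraction of its directional
features — those with |log2FC| above a threshold (default 0.1) — whose
fold change is positive. Under the symmetric null the up/down split is
Binomial(n, 1/2), so significance comes from a two-sided exact binomial
test (minimum-likelihood convention, as in R's ``binom.test``), with a
Clopper-Pearson 95% interval on the proportion and a Bonferroni
correction across the four RNA classes compared (BSJ, FSJ, BSJ-host
genes, all genes).

The module also houses the supporting comparisons: a rank-sum test of
per-feature mean expression between groups, the Spearman correlation of
BSJ and flanking-FSJ fold changes, and a rank-sum comparison of the two
fold-change distributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ImbalanceResult:
    """Directional summary of one RNA class's fold changes."""

    rna_class: str
    k_up: int
    k_down: int
    n_directional: int
    imbalance: float
    ci_low: float
    ci_high: float
    p: float
    p_bonferroni: float
    threshold: float = 0.1

    @property
    def degenerate(self) -> bool:
        """True when no feature passed the directionality threshold."""
        return self.n_directional == 0


def imbalance(
    log2fcs: Iterable[float],
    threshold: float = 0.1,
    n_tests: int = 4,
    rna_class: str = "",
) -> ImbalanceResult:
    """Fold-change imbalance with its exact binomial null.

    ``k_up`` counts fold changes > ``threshold``, ``k_down`` those
    < -``threshold``; the imbalance is k_up / (k_up + k_down), 0.5 under
    the symmetric null. With no directional features the result is
    returned with ``degenerate=True`` and NaN statistics rather than a
    silent 0.5.
    """
    fcs = np.asarray(list(log2fcs), dtype=float)
    if fcs.size and not np.isfinite(fcs).all():
        raise ValueError("fold changes must be finite")
    k_up = int((fcs > threshold).sum())
    k_down = int((fcs < -threshold).sum())
    n = k_up + k_down
    if n == 0:
        return ImbalanceResult(
            rna_class=rna_class,
            k_up=0,
            k_down=0,
            n_directional=0,
            imbalance=np.nan,
            ci_low=np.nan,
            ci_high=np.nan,
            p=np.nan,
            p_bonferroni=np.nan,
            threshold=threshold,
        )
    test = stats.binomtest(k_up, n, 0.5, alternative="two-sided")
    ci = test.proportion_ci(confidence_level=0.95, method="exact")
    return ImbalanceResult(
        rna_class=rna_class,
        k_up=k_up,
        k_down=k_down,
        n_directional=n,
        imbalance=k_up / n,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        p=float(test.pvalue),
        p_bonferroni=min(1.0, n_tests * float(test.pvalue)),
        threshold=threshold,
    )


def rank_sum(x, y) -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum test.

    Exact enumeration for small tie-free samples (both sides <= 50),
    normal approximation with tie correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.r_[x, y]
    has_ties = np.unique(pooled).size < pooled.size
    small = max(x.size, y.size) <= 50
    method = "exact" if (small and not has_ties) else "asymptotic"
    u0 = x.size * y.size / 2.0
    with np.errstate(invalid="ignore"):
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    p = float(res.pvalue)
    if not np.isfinite(p):
        # zero rank variance (e.g. every pooled value tied): null centre
        p = 1.0
    if float(res.statistic) == u0:
        p = 1.0
    return float(res.statistic), p


def expression_shift(
    normalized_expr: pd.DataFrame,
    groups: pd.Series,
    case_label: str = "PD",
) -> tuple[float, float]:
    """Rank-sum comparison of per-feature mean expression between groups.

    ``normalized_expr`` is features x samples, already restricted to the
    features that entered differential expression. Each feature's mean
    normalized expression is computed within cases and within controls;
    the two per-feature mean vectors are compared by an unpaired
    rank-sum test.
    """
    if normalized_expr.shape[0] < 2:
        raise ValueError("need at least two features")
    groups = groups.reindex(normalized_expr.columns)
    case_means = normalized_expr.loc[:, groups == case_label].mean(axis=1)
    ctrl_means = normalized_expr.loc[:, groups != case_label].mean(axis=1)
    return rank_sum(case_means.to_numpy(), ctrl_means.to_numpy())


def fc_correlation(bsj_fc, fsj_fc) -> tuple[float, float]:
    """Spearman correlation of paired BSJ and FSJ fold changes.

    Returns (rho, rho squared); the squared form is what summary tables
    usually print.
    """
    b = np.asarray(bsj_fc, dtype=float)
    f = np.asarray(fsj_fc, dtype=float)
    if b.size != f.size:
        raise ValueError("fold-change vectors must be paired (equal length)")
    if b.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.unique(b).size == 1 or np.unique(f).size == 1:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho = float(stats.spearmanr(b, f).statistic)
    return rho, rho**2


def fc_shift(bsj_fc, fsj_fc) -> tuple[float, float]:
    """Unpaired rank-sum comparison of BSJ vs FSJ fold-change distributions."""
    return rank_sum(np.asarray(bsj_fc, float), np.asarray(fsj_fc, float))


def class_panel(
    de_results: Mapping[str, pd.DataFrame],
    host_genes: Iterable[str] = (),
    threshold: float = 0.1,
    n_tests: int = 4,
) -> list[ImbalanceResult]:
    """Four-class imbalance panel: BSJ, FSJ, BSJ-host genes, all genes.

    ``de_results`` must supply DE tables (with ``log2FC`` and ``p``
    columns) under the keys ``"gene"``, ``"BSJ"`` and ``"FSJ"``; the
    BSJ-host class is the gene table restricted to ``host_genes``. Only
    features with a non-missing p (i.e. converged fits) contribute.
    Classes with no directional features are reported as degenerate
    rather than dropped.
    """
    for key in ("gene", "BSJ", "FSJ"):
        if key not in de_results:
            raise ValueError(f"missing DE results for class {key!r}")

    def _fcs(table: pd.DataFrame) -> np.ndarray:
        return table.loc[table["p"].notna(), "log2FC"].to_numpy()

    gene_table = de_results["gene"]
    host_set = set(host_genes)
    host_table = gene_table.loc[gene_table.index.isin(host_set)]

    panel = [
        imbalance(_fcs(de_results["BSJ"]), threshold, n_tests, rna_class="BSJ"),
        imbalance(_fcs(de_results["FSJ"]), threshold, n_tests, rna_class="FSJ"),
        imbalance(_fcs(host_table), threshold, n_tests, rna_class="BSJ-host"),
        imbalance(_fcs(gene_table), threshold, n_tests, rna_class="gene"),
    ]
    return panel


def panel_to_frame(panel: list[ImbalanceResult]) -> pd.DataFrame:
    rows = [
        {
            "rna_class": r.rna_class,
            "k_up": r.k_up,
            "k_down": r.k_down,
            "n_directional": r.n_directional,
            "imbalance": r.imbalance,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "p": r.p,
            "p_bonferroni": r.p_bonferroni,
        }
        for r in panel
    ]
    return pd.DataFrame(rows)
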