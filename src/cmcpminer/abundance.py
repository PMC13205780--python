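"""Per-cohort quantification and differential abundance of CMCP families.

Counts of reads assigned to CMCP-bearing contigs are normalised for
sequencing depth with DESeq-style median-of-ratios size factors and
tested feature by feature with a negative-binomial Wald test (log link,
case/control design, per-feature method-of-moments dispersion),
Benjamini-Hochberg adjusted within each cohort.  This is a plain
NB-Wald test: DESeq2's dispersion shrinkage and LFC moderation are
deliberately not replicated — downstream meta-analysis consumes only
the fold-change sign, the p-value and the sample sizes.

Read assignment is a simplified exact k-mer matcher standing in for a
full aligner: a read is credited to the contig sharing the most exact
21-mers on either strand; ties and no-hits are left unassigned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from cmcpminer.seq_io import SequenceRecord, reverse_complement

DISPERSION_FLOOR = 1e-8
DEFAULT_KMER = 21


@dataclass
class CohortStats:
    """Per-feature differential-abundance results for one cohort."""

    cohort: str
    table: pd.DataFrame  # index: feature; columns: lfc, se, pvalue, padj,
    #                      direction, highlight, flagged
    n_case: int
    n_control: int


def count_reads(
    reads: Sequence[SequenceRecord],
    contigs: Sequence[SequenceRecord],
    feature_of_contig: Mapping[str, str],
    k: int = DEFAULT_KMER,
) -> pd.Series:
    """Assign reads to contigs by shared exact k-mers; aggregate by feature.

    A read goes to the contig with which it shares the most k-mers
    (either strand); reads tying between contigs or matching none are
    dropped.  Returns one count per feature.
    """
    kmer_index: dict[str, set[str]] = {}
    for c in contigs:
        s = c.residues
        kmers = {s[i: i + k] for i in range(len(s) - k + 1)}
        rc = reverse_complement(s)
        kmers |= {rc[i: i + k] for i in range(len(rc) - k + 1)}
        kmer_index[c.id] = kmers
    features = sorted(set(feature_of_contig.values()))
    counts = pd.Series(0, index=features, dtype=int)
    for r in reads:
        if len(r.residues) < k:
            continue
        rk = {r.residues[i: i + k] for i in range(len(r.residues) - k + 1)}
        best_contig, best_n, tied = None, 0, False
        for cid, ck in kmer_index.items():
            n = len(rk & ck)
            if n > best_n:
                best_contig, best_n, tied = cid, n, False
            elif n == best_n and n > 0:
                tied = True
        if best_contig is not None and not tied:
            feat = feature_of_contig.get(best_contig)
            if feat is not None:
                counts[feat] += 1
    return counts


def relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample proportions; zero-total samples are dropped with a warning."""
    totals = counts.sum(axis=0)
    zero = totals[totals == 0].index
    if len(zero):
        warnings.warn(f"dropping zero-total samples: {list(zero)}")
        counts = counts.drop(columns=zero)
        totals = totals.drop(zero)
    return counts / totals


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios depth-normalisation factors (DESeq convention).

    The reference is the per-feature geometric mean across samples,
    computed over features with no zero count; each sample's factor is
    the median ratio of its counts to the reference.  When no feature is
    zero-free the geometric means fall back to positive counts only
    (flagged with a warning).
    """
    x = counts.to_numpy(dtype=float)
    nonzero_rows = (x > 0).all(axis=1)
    if nonzero_rows.any():
        logref = np.log(x[nonzero_rows]).mean(axis=1)
        ratios = np.log(x[nonzero_rows]) - logref[:, None]
    else:
        warnings.warn("no all-nonzero feature; using positive counts only")
        logx = np.full_like(x, np.nan)
        np.log(x, out=logx, where=x > 0)
        logref = np.nanmean(logx, axis=1)
        ratios = logx - logref[:, None]
        keep = ~np.all(np.isnan(ratios), axis=0)
        if not keep.all():
            raise ValueError("some samples share no positive feature with the reference")
    factors = np.exp(np.nanmedian(ratios, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _mom_dispersion(q: np.ndarray, groups: np.ndarray) -> float:
    """Pooled method-of-moments NB dispersion from normalised counts."""
    alphas = []
    for g in np.unique(groups):
        v = q[groups == g]
        if len(v) < 2:
            continue
        mu = v.mean()
        if mu <= 0:
            continue
        alphas.append((v.var(ddof=1) - mu) / mu**2)
    if not alphas:
        return DISPERSION_FLOOR
    return max(float(np.mean(alphas)), DISPERSION_FLOOR)


def diff_abundance(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    cohort: str,
    alpha: float = 0.05,
    lfc_highlight: float = 2.0,
) -> CohortStats:
    """Case-vs-control NB-Wald differential abundance within one cohort.

    ``meta`` must carry columns ``cohort`` and ``condition`` (values
    ``case``/``control``) indexed by sample id.  Returns per-feature
    log2 fold changes, Wald p-values, BH-adjusted p-values, the
    direction sign and the volcano highlight flag
    (|LFC| > ``lfc_highlight`` and padj < ``alpha``).
    """
    samples = meta.index[meta["cohort"] == cohort]
    samples = [s for s in samples if s in counts.columns]
    sub = counts[samples]
    cond = meta.loc[samples, "condition"]
    is_case = (cond == "case").to_numpy().astype(float)
    n_case, n_control = int(is_case.sum()), int((1 - is_case).sum())
    if n_case < 2 or n_control < 2:
        raise ValueError(f"cohort {cohort!r} needs >= 2 samples per condition")
    sf = size_factors(sub)
    offset = np.log(sf.to_numpy())
    design = sm.add_constant(is_case)

    rows = []
    for feat, y in sub.iterrows():
        yv = y.to_numpy(dtype=float)
        q = yv / sf.to_numpy()
        if yv.sum() == 0:
            rows.append((feat, 0.0, np.nan, 1.0, 0, True))
            continue
        disp = _mom_dispersion(q, is_case)
        try:
            model = sm.GLM(
                yv, design, family=sm.families.NegativeBinomial(alpha=disp),
                offset=offset,
            )
            res = model.fit()
            coef, se = res.params[1], res.bse[1]
            if not np.isfinite(coef) or not np.isfinite(se) or se > 1e3:
                raise ValueError("unstable fit")
            lfc = coef / np.log(2)
            se2 = se / np.log(2)
            p = float(2 * stats.norm.sf(abs(coef / se)))
            rows.append((feat, float(lfc), float(se2), p, int(np.sign(lfc)), False))
        except Exception:
            mc = q[is_case == 1].mean()
            mh = q[is_case == 0].mean()
            lfc = float(np.log2((mc + 0.5) / (mh + 0.5)))
            rows.append((feat, lfc, np.nan, 1.0, int(np.sign(lfc)), True))
    table = pd.DataFrame(
        rows, columns=["feature", "lfc", "se", "pvalue", "direction", "flagged"],
    ).set_index("feature")
    table["padj"] = multipletests(table["pvalue"].to_numpy(), method="fdr_bh")[1]
    table["highlight"] = (table["lfc"].abs() > lfc_highlight) & (table["padj"] < alpha)
    table = table[["lfc", "se", "pvalue", "padj", "direction", "highlight", "flagged"]]
    return CohortStats(cohort=cohort, table=table,
                       n_case=n_case, n_control=n_control)
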