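"""Sample-size-weighted-Z fixed-effects meta-analysis across cohorts.

Each cohort contributes a signed Z derived from its two-sided p-value
and fold-change direction, Z = sign * Phi^-1(1 - p/2); cohorts are
combined with weights w_i = sqrt(N_i) (N_i = cases + controls):

    Z_meta = sum(w_i Z_i) / sqrt(sum(w_i^2)),   p_meta = 2(1 - Phi(|Z_meta|))

(the METAL sample-size scheme; an inverse-variance scheme is available
as an option).  A feature absent from a cohort contributes a "?" to the
per-cohort direction string and is excluded from the sum.  Enrichment
classes use the raw meta-p at the 0.05 cut-off by default; optional BH
adjustment across features can be switched on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from cmcpminer.abundance import CohortStats

P_FLOOR = 1e-300

CASE_ENRICHED = "case_enriched"
CONTROL_ENRICHED = "control_enriched"
NOT_SIGNIFICANT = "ns"


def cohort_z(p: float, direction: int, p_floor: float = P_FLOOR) -> float:
    """Signed Z from a two-sided p-value and an effect direction sign."""
    if not 0 <= p <= 1:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if direction not in (-1, 0, 1):
        raise ValueError("direction must be -1, 0 or +1")
    if p == 0:
        warnings.warn(f"p = 0 clamped to {p_floor}")
        p = p_floor
    return float(direction * stats.norm.isf(p / 2))


@dataclass
class MetaRow:
    feature: str
    z_meta: float
    p_meta: float
    direction_string: str
    enrichment: str
    cohort_z: list[float] = field(default_factory=list)  # NaN where absent
    cohort_n: list[int] = field(default_factory=list)


def combine_weighted_z(
    zs: Sequence[float], ns: Sequence[int], scheme: str = "samplesize",
    ses: Optional[Sequence[float]] = None,
) -> tuple[float, float]:
    """Combine per-cohort signed Z statistics into one (Z_meta, p_meta).

    NaN entries (feature absent from that cohort) are excluded.  The
    default sample-size scheme weights by sqrt(N_i); the
    ``inverse_variance`` scheme needs per-cohort effect standard errors.
    """
    zs = np.asarray(zs, float)
    ns = np.asarray(ns, float)
    ok = np.isfinite(zs)
    if not ok.any():
        raise ValueError("no cohort provides a finite Z")
    if scheme == "samplesize":
        w = np.sqrt(ns[ok])
        z_meta = float((w * zs[ok]).sum() / np.sqrt((w**2).sum()))
    elif scheme == "inverse_variance":
        if ses is None:
            raise ValueError("inverse-variance scheme requires standard errors")
        se = np.asarray(ses, float)[ok]
        w = 1.0 / se**2
        # zs here are effect/se; recover effects, combine, re-standardise
        eff = zs[ok] * se
        mean = (w * eff).sum() / w.sum()
        z_meta = float(mean * np.sqrt(w.sum()))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    p_meta = float(2 * stats.norm.sf(abs(z_meta)))
    return z_meta, p_meta


def _empirical_null_calibrate(z_by_feature: dict[str, list[float]],
                              n_cohorts: int,
                              min_features: int = 10) -> None:
    """Location/scale empirical-null correction of per-cohort Z columns.

    Median-of-ratios normalisation is mildly compositional: features
    with real effects contaminate the size factors and shift every null
    feature's Z by a common small offset, which the weighted-Z
    combination then amplifies by sqrt(#cohorts).  Following the
    genomic-control / empirical-null tradition, each cohort's Z column
    is re-centred at its median and re-scaled by 1.4826 x MAD, both
    robust to a modest fraction of genuinely differential features.
    Cohorts contributing fewer than ``min_features`` finite Z values
    are left untouched.  Modifies the mapping in place.
    """
    feats = list(z_by_feature)
    for c in range(n_cohorts):
        col = np.array([z_by_feature[f][c] for f in feats])
        finite = col[np.isfinite(col)]
        if finite.size < min_features:
            continue
        med = float(np.median(finite))
        mad = float(np.median(np.abs(finite - med)))
        scale = 1.4826 * mad
        if scale < 1e-6:
            continue
        for f in feats:
            z = z_by_feature[f][c]
            if np.isfinite(z):
                z_by_feature[f][c] = (z - med) / scale


def classify_enrichment(
    cohort_stats: Sequence[CohortStats],
    alpha: float = 0.05,
    scheme: str = "samplesize",
    adjust_meta: bool = False,
    empirical_null: bool = True,
) -> pd.DataFrame:
    """Meta-analyse all features across cohorts and classify enrichment.

    Per-cohort symbols follow the forest-plot convention: "+" when the
    cohort's padj < ``alpha`` with positive LFC, "-" when padj < alpha
    with negative LFC, "?" otherwise (including absence).  Classes:
    ``case_enriched`` when the meta-p clears the cut-off with Z_meta > 0,
    ``control_enriched`` with Z_meta < 0, else ``ns``.  With
    ``empirical_null`` (default) each cohort's Z column is first given a
    robust location/scale correction (see
    :func:`_empirical_null_calibrate`).
    """
    features: list[str] = []
    for cs in cohort_stats:
        for f in cs.table.index:
            if f not in features:
                features.append(f)
    z_of: dict[str, list[float]] = {}
    n_of: dict[str, list[int]] = {}
    sym_of: dict[str, list[str]] = {}
    for feat in features:
        zs, ns, symbols = [], [], []
        for cs in cohort_stats:
            if feat not in cs.table.index:
                zs.append(np.nan)
                ns.append(cs.n_case + cs.n_control)
                symbols.append("?")
                continue
            r = cs.table.loc[feat]
            direction = int(r["direction"])
            if r["flagged"] or direction == 0:
                zs.append(0.0 if not r["flagged"] else np.nan)
            else:
                zs.append(cohort_z(float(r["pvalue"]), direction))
            ns.append(cs.n_case + cs.n_control)
            if r["padj"] < alpha and r["lfc"] > 0:
                symbols.append("+")
            elif r["padj"] < alpha and r["lfc"] < 0:
                symbols.append("-")
            else:
                symbols.append("?")
        z_of[feat], n_of[feat], sym_of[feat] = zs, ns, symbols
    if empirical_null and z_of:
        _empirical_null_calibrate(z_of, len(cohort_stats))
    rows: list[MetaRow] = []
    for feat in features:
        try:
            z_meta, p_meta = combine_weighted_z(z_of[feat], n_of[feat],
                                                scheme=scheme)
        except ValueError:
            warnings.warn(f"feature {feat!r} absent from every cohort; dropped")
            continue
        rows.append(MetaRow(
            feature=feat, z_meta=z_meta, p_meta=p_meta,
            direction_string="".join(sym_of[feat]), enrichment="",
            cohort_z=z_of[feat], cohort_n=n_of[feat],
        ))
    p_cut = np.array([r.p_meta for r in rows])
    if adjust_meta and len(rows):
        p_cut = multipletests(p_cut, method="fdr_bh")[1]
    out = []
    for r, p_eff in zip(rows, p_cut):
        if p_eff < alpha and r.z_meta > 0:
            r.enrichment = CASE_ENRICHED
        elif p_eff < alpha and r.z_meta < 0:
            r.enrichment = CONTROL_ENRICHED
        else:
            r.enrichment = NOT_SIGNIFICANT
        row = {
            "feature": r.feature, "z_meta": r.z_meta, "p_meta": r.p_meta,
            "class": r.enrichment, "direction_string": r.direction_string,
        }
        for i, (z, n) in enumerate(zip(r.cohort_z, r.cohort_n), start=1):
            row[f"z_cohort{i}"] = z
            row[f"n_cohort{i}"] = n
        out.append(row)
    df = pd.DataFrame(out)
    if len(df):
        df = df.set_index("feature")
    return df


def write_meta_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format="%.6g")
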