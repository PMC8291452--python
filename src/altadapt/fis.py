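"""Functional-importance scoring and gene prioritization of candidate variants.

Each candidate adaptive variant gets, per annotation method (CADD, GERP,
optionally SIFT/PolyPhen), a functional importance score

    FIS = CS * |dAF|

where CS is the method's conservation score after two rules: negative
GERP scores (evolutionary neutrality) are floored to 0, and variants with
protein-changing (CPS) or expression-regulating (RGE) effects receive the
maximum CS observed for that method over the candidate set. Variants are
ranked per method by FIS (rank 1 = highest), ranks are averaged over
methods, and each gene is represented by its best-ranked ("key") variant.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

log = logging.getLogger(__name__)

DEFAULT_METHODS = ("cadd", "gerp")
#: Methods whose negative scores denote neutrality and are floored to 0.
FLOORED_METHODS = frozenset({"gerp"})


def fis_score(cs, delta_af):
    """FIS = CS * |dAF| (CS already floored/weighted)."""
    return np.asarray(cs, dtype=float) * np.abs(np.asarray(delta_af, dtype=float))


def weight_cs(scores, effect_classes, method: str) -> np.ndarray:
    """Effective conservation scores for one method over the candidate set.

    Negative scores are floored to 0 for floored methods (GERP); CPS and
    RGE variants then receive the maximum score observed across the set,
    while UCE variants keep their own.
    """
    cs = np.asarray(scores, dtype=float)
    effect_classes = np.asarray(effect_classes)
    if method.lower() in FLOORED_METHODS:
        cs = np.where(np.isfinite(cs) & (cs < 0), 0.0, cs)
    finite = cs[np.isfinite(cs)]
    if finite.size == 0:
        return cs
    max_cs = finite.max()
    boosted = np.isin(effect_classes, ("CPS", "RGE"))
    return np.where(boosted, max_cs, cs)


def rank_aggregate(fis_matrix: pd.DataFrame) -> pd.Series:
    """Mean rank over methods; rank 1 = highest FIS within each method.

    ``fis_matrix`` is variants x methods. Ties share the average rank.
    Missing entries are ignored per variant; variants missing every method
    are dropped with a warning. Lower aggregated rank = higher priority.
    """
    ranks = pd.DataFrame(index=fis_matrix.index, columns=fis_matrix.columns, dtype=float)
    for col in fis_matrix.columns:
        vals = fis_matrix[col].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        if not ok.any():
            log.warning("method %r has no usable FIS values; dropped", col)
            continue
        r = np.full(vals.shape, np.nan)
        r[ok] = rankdata(-vals[ok], method="average")
        ranks[col] = r
    agg = ranks.mean(axis=1, skipna=True)
    dropped = agg.index[agg.isna()]
    for vid in dropped:
        log.warning("variant %r has no FIS under any method; excluded", vid)
    return agg.dropna()


def build_fis_table(agvs: pd.DataFrame, methods=DEFAULT_METHODS) -> pd.DataFrame:
    """Full per-variant FIS/rank table from a candidate-variant frame.

    ``agvs`` needs columns: variant_id, delta_af, effect_class, position,
    optionally cms and one column per method score. Returns the frame
    indexed by variant_id with fis_<m>, rank aggregate, and inputs kept.
    """
    df = agvs.set_index("variant_id", drop=False)
    fis_cols = {}
    for m in methods:
        if m not in df.columns:
            log.warning("method column %r absent; dropped from aggregate", m)
            continue
        cs = weight_cs(df[m].to_numpy(), df["effect_class"].to_numpy(), m)
        fis_cols[m] = fis_score(cs, df["delta_af"].to_numpy())
        df[f"fis_{m}"] = fis_cols[m]
    if not fis_cols:
        raise ValueError("no usable annotation method columns")
    fis_matrix = pd.DataFrame(fis_cols, index=df.index)
    df["rank"] = rank_aggregate(fis_matrix)
    return df[df["rank"].notna()].copy()


def prioritize_genes(fis_table: pd.DataFrame) -> pd.DataFrame:
    """Per-gene key variant and gene ordering by functional importance.

    The key variant of a gene is its best-priority (lowest mean rank)
    candidate; genes are ordered by their key variant. Ties break by
    (mean rank, CMS descending when present, genomic position).
    """
    df = fis_table.copy()
    if "gene" not in df.columns or df["gene"].isna().any():
        raise ValueError("every candidate variant must carry a gene assignment")
    if "cms" not in df.columns:
        df["cms"] = 0.0
    df = df.sort_values(["rank", "cms", "position"],
                        ascending=[True, False, True], kind="mergesort")
    key = df.groupby("gene", sort=False).head(1)
    out = key[["gene", "variant_id", "rank", "cms", "position", "effect_class"]].copy()
    out = out.rename(columns={"variant_id": "key_variant"})
    out = out.sort_values(["rank", "cms", "position"],
                          ascending=[True, False, True], kind="mergesort")
    out["gene_rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)
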