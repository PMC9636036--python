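"""Count-level preprocessing: depth filtering, smoothing, universe intersection."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import BulkMethylome, ReferenceAtlas, parse_cpg_id

log = logging.getLogger(__name__)

DEFAULT_MIN_DEPTH = 10
DEFAULT_SMOOTH_WINDOW_BP = 500
DEFAULT_MAX_MISSING_FRACTION = 0.2


def compute_beta(
    methylated: pd.DataFrame,
    total: pd.DataFrame,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> pd.DataFrame:
    """Beta = methylated/total where depth >= min_depth, else NaN.

    Sites with a depth of less than ``min_depth`` (default 10) are marked
    missing rather than dropped, so the missingness rule can be applied on
    the shared universe later.
    """
    if methylated.shape != total.shape:
        raise ValueError("methylated and total matrices must share a shape")
    m = methylated.to_numpy(dtype=float)
    t = total.to_numpy(dtype=float)
    if (m < 0).any() or (t < 0).any():
        raise ValueError("negative read counts")
    bad = m > t
    if bad.any():
        i = int(np.argwhere(bad)[0, 0])
        raise ValueError(f"methylated > total at CpG {methylated.index[i]}")
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(t >= min_depth, m / t, np.nan)
    return pd.DataFrame(beta, index=methylated.index, columns=methylated.columns)


def _positions_frame(cpg_ids: pd.Index) -> pd.DataFrame:
    parsed = [parse_cpg_id(c) for c in cpg_ids]
    return pd.DataFrame(
        {"chrom": [p[0] for p in parsed], "pos": [p[1] for p in parsed]}, index=cpg_ids
    )


def smooth_betas(
    betas: pd.DataFrame,
    positions: pd.DataFrame | None = None,
    window_bp: int = DEFAULT_SMOOTH_WINDOW_BP,
    coverage: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Coverage-weighted fixed-window mean smoother.

    Each beta is replaced by the coverage-weighted mean of non-missing
    betas at CpGs within +/- ``window_bp`` on the same chromosome (the CpG
    itself included).  With no coverage matrix all sites weigh equally.  A
    CpG with no neighbors inside the window keeps its own value; a window
    of 0 bp is the identity transform.
    """
    if positions is None:
        positions = _positions_frame(betas.index)
    out = betas.to_numpy(dtype=float).copy()
    vals = betas.to_numpy(dtype=float)
    w = None if coverage is None else coverage.to_numpy(dtype=float)

    for chrom, grp in positions.groupby("chrom", sort=False):
        rows = betas.index.get_indexer(grp.index)
        pos = grp["pos"].to_numpy()
        order = np.argsort(pos, kind="stable")
        rows, pos = rows[order], pos[order]
        lo = np.searchsorted(pos, pos - window_bp, side="left")
        hi = np.searchsorted(pos, pos + window_bp, side="right")
        for k, r in enumerate(rows):
            nb = rows[lo[k] : hi[k]]
            v = vals[nb]
            wt = np.ones_like(v) if w is None else w[nb]
            mask = ~np.isnan(v)
            for j in range(v.shape[1]):
                col_mask = mask[:, j]
                if col_mask.any():
                    wj = wt[col_mask, j]
                    tot = wj.sum()
                    if tot > 0:
                        out[r, j] = (v[col_mask, j] * wj).sum() / tot
    return pd.DataFrame(out, index=betas.index, columns=betas.columns)


def handle_missing(
    betas: pd.DataFrame, max_missing_fraction: float = DEFAULT_MAX_MISSING_FRACTION
) -> pd.DataFrame:
    """Drop CpGs missing in more than the allowed fraction of samples;
    impute the rest with the CpG's cross-sample mean."""
    frac = betas.isna().mean(axis=1)
    kept = betas.loc[frac <= max_missing_fraction]
    if kept.isna().to_numpy().any():
        means = kept.mean(axis=1)
        kept = kept.apply(lambda col: col.fillna(means), axis=0)
    n_drop = len(betas) - len(kept)
    if n_drop:
        log.info("dropped %d CpGs missing in >%.0f%% of samples", n_drop, 100 * max_missing_fraction)
    return kept


def intersect_universe(
    atlas: ReferenceAtlas,
    bulk: BulkMethylome,
    max_missing_fraction: float = DEFAULT_MAX_MISSING_FRACTION,
) -> tuple[ReferenceAtlas, BulkMethylome]:
    """Restrict both sides to the CpGs investigated in both, same order.

    CpGs missing (NaN beta) in more than ``max_missing_fraction`` of the
    samples of either side are dropped from both; remaining missing values
    are mean-imputed per CpG.
    """
    common = atlas.cpg_ids.intersection(bulk.cpg_ids)
    if len(common) == 0:
        raise ValueError(
            f"empty CpG intersection (atlas universe {atlas.n_cpgs}, "
            f"bulk universe {bulk.n_cpgs})"
        )
    common = atlas.cpg_ids[atlas.cpg_ids.isin(common)]  # preserve atlas order

    def _clean(obj):
        sub = obj.subset_cpgs(common)
        if sub.betas is None:
            return sub, pd.Index(common)
        frac = sub.betas.isna().mean(axis=1)
        keep = sub.betas.index[frac <= max_missing_fraction]
        return sub, keep

    atlas_sub, keep_a = _clean(atlas)
    bulk_sub, keep_b = _clean(bulk)
    keep = keep_a.intersection(keep_b)
    keep = common[common.isin(keep)]
    atlas_out = atlas_sub.subset_cpgs(keep)
    bulk_out = bulk_sub.subset_cpgs(keep)
    for obj in (atlas_out, bulk_out):
        if obj.betas is not None and obj.betas.isna().to_numpy().any():
            means = obj.betas.mean(axis=1)
            obj.betas = obj.betas.apply(lambda col: col.fillna(means), axis=0)
    return atlas_out, bulk_out
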