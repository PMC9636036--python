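"""Differential methylation calling and regulatory-element interpretation.

Two-group comparisons of methylation proportions use a beta-binomial Wald
test: per-group proportions are pooled over replicates (optionally
window-smoothed), dispersion is estimated by method of moments and shrunk
toward the local (+/-500 bp) mean, and the effect/SE statistic is referred
to the normal distribution.  CpGs map to regulatory elements within an
inclusive +/-1,250 bp window; RE target genes feed a hypergeometric GO
enrichment with Benjamini-Hochberg correction, and a paired t test probes
hypomethylation near dendritic-cell activation markers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ReferenceAtlas, parse_cpg_id, state_of_class
from .preprocess import smooth_betas
from .signature import SignatureMatrix

log = logging.getLogger(__name__)

DEFAULT_P_THRESHOLD = 0.001
DEFAULT_RE_WINDOW_BP = 1250
LOCAL_DISPERSION_WINDOW_BP = 500
DISPERSION_SHRINKAGE = 0.5

# Activation/maturation markers of immunogenic dendritic cells; IL12 is a
# heterodimer encoded by IL12A and IL12B.
DC_ACTIVATION_MARKERS = ("HLA-DRA", "CCR7", "CD40", "CCL22", "IFNG", "IL12", "CD86")
MARKER_EXPANSION = {"IL12": ("IL12A", "IL12B")}
_PAIR_EQUIV = {"macrophage": "monocyte"}


@dataclass
class REMap:
    """Regulatory-element intervals (0-based half-open) with target genes."""

    intervals: list[tuple[str, int, int, str]]
    re_targets: dict[str, str]
    source: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for chrom, start, end, rid in self.intervals:
            if not start < end:
                raise ValueError(f"degenerate RE interval {rid}: [{start}, {end})")
            if rid in seen:
                raise ValueError(f"duplicate re_id {rid}")
            seen.add(rid)

    @classmethod
    def from_genome(cls, genome) -> "REMap":
        return cls(
            intervals=list(genome.re_intervals),
            re_targets=dict(genome.re_targets),
            source="toy-genome",
        )

    def chromosomes(self) -> set[str]:
        return {c for c, *_ in self.intervals}

    def res_targeting(self, gene: str) -> list[str]:
        return [rid for rid, g in self.re_targets.items() if g == gene]


def _pooled_stats(meth: np.ndarray, total: np.ndarray):
    """Pooled proportion, MoM beta-binomial dispersion, and variance terms.

    ``meth``/``total`` are CpG x replicate count matrices of one group.
    """
    N = total.sum(axis=1)
    p_hat = np.divide(meth.sum(axis=1), N, out=np.zeros(len(N)), where=N > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_rep = np.where(total > 0, meth / total, np.nan)
    s2 = np.nanvar(p_rep, axis=1, ddof=1)
    inv_n = np.nanmean(np.where(total > 0, 1.0 / total, np.nan), axis=1)
    pq = p_hat * (1 - p_hat)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (s2 / pq - inv_n) / (1.0 - inv_n)
    phi = np.where(np.isfinite(phi), phi, 0.0)
    phi = np.clip(phi, 0.0, 0.99)
    return p_hat, phi, N


def _shrink_local(values: np.ndarray, chroms: np.ndarray, positions: np.ndarray,
                  window_bp: int = LOCAL_DISPERSION_WINDOW_BP,
                  weight: float = DISPERSION_SHRINKAGE) -> np.ndarray:
    """Shrink per-CpG values toward their local window mean."""
    out = values.copy()
    for chrom in pd.unique(chroms):
        sel = np.flatnonzero(chroms == chrom)
        pos = positions[sel]
        order = np.argsort(pos, kind="stable")
        sel, pos = sel[order], pos[order]
        v = values[sel]
        csum = np.concatenate([[0.0], np.cumsum(v)])
        lo = np.searchsorted(pos, pos - window_bp, side="left")
        hi = np.searchsorted(pos, pos + window_bp, side="right")
        local_mean = (csum[hi] - csum[lo]) / (hi - lo)
        out[sel] = (1 - weight) * v + weight * local_mean
    return out


def call_dmcs(
    atlas: ReferenceAtlas,
    class_a: str,
    class_b: str,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    smoothing: bool = True,
    return_all: bool = False,
) -> pd.DataFrame:
    """Beta-binomial Wald test of methylation proportions between two classes.

    Returns sites with p < ``p_threshold`` (or the full per-CpG table with
    ``return_all``): columns cpg_id, mean_a, mean_b, effect, stat, p,
    category, direction.  Sites with zero coverage in either group are
    skipped (counted in the log).
    """
    if atlas.methylated is None or atlas.total is None:
        raise ValueError("count data required for DMC calling")
    parts = {}
    for cls in (class_a, class_b):
        cols = atlas.samples_of_class(cls)
        if len(cols) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 replicates")
        parts[cls] = (
            atlas.methylated[cols].to_numpy(dtype=float),
            atlas.total[cols].to_numpy(dtype=float),
        )

    pa, phia, Na = _pooled_stats(*parts[class_a])
    pb, phib, Nb = _pooled_stats(*parts[class_b])
    valid = (Na > 0) & (Nb > 0)
    n_skip = int((~valid).sum())
    if n_skip:
        log.info("skipping %d CpGs with zero coverage in a group", n_skip)

    parsed = [parse_cpg_id(c) for c in atlas.cpg_ids]
    chroms = np.array([p[0] for p in parsed], dtype=object)
    positions = np.array([p[1] for p in parsed], dtype=np.int64)

    if smoothing:
        idx = atlas.cpg_ids
        for key, (m, t) in parts.items():
            pooled = pd.DataFrame(
                {"p": np.divide(m.sum(axis=1), t.sum(axis=1),
                                out=np.zeros(len(idx)), where=t.sum(axis=1) > 0)},
                index=idx,
            )
            cov = pd.DataFrame({"p": t.sum(axis=1)}, index=idx)
            sm = smooth_betas(pooled, coverage=cov)["p"].to_numpy()
            if key == class_a:
                pa = sm
            else:
                pb = sm

    phia = _shrink_local(phia, chroms, positions)
    phib = _shrink_local(phib, chroms, positions)

    def _var(p, phi, meth_total):
        m, t = meth_total
        N = t.sum(axis=1)
        p_floor = np.clip(p, 1.0 / (N + 1), 1.0 - 1.0 / (N + 1))
        pq = p_floor * (1 - p_floor)
        per_rep = t * pq[:, None] * (1.0 + (t - 1.0) * phi[:, None])
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(N > 0, per_rep.sum(axis=1) / N**2, np.nan)

    va = _var(pa, phia, parts[class_a])
    vb = _var(pb, phib, parts[class_b])
    effect = pa - pb
    se = np.sqrt(va + vb)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, effect / se, 0.0)
    pval = 2.0 * stats.norm.sf(np.abs(stat))
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)

    sa, sb = state_of_class(class_a), state_of_class(class_b)
    if {sa, sb} == {"TIIC", "PBMC"}:
        category = "TIIC-PBMC"
    elif sa == sb == "TIIC":
        category = "TIIC-TIIC"
    elif sa == sb == "PBMC":
        category = "PBMC-PBMC"
    else:
        category = f"{sa}-{sb}"

    tiic_minus_pbmc = effect if sa == "TIIC" else -effect
    direction = np.where(tiic_minus_pbmc < 0, "hypo-in-TIIC", "hyper-in-TIIC")

    out = pd.DataFrame(
        {
            "cpg_id": atlas.cpg_ids,
            "mean_a": pa,
            "mean_b": pb,
            "effect": effect,
            "stat": stat,
            "p": pval,
            "category": category,
            "direction": direction if category == "TIIC-PBMC" else "",
        }
    ).loc[valid]
    if return_all:
        return out.reset_index(drop=True)
    return out.loc[out["p"] < p_threshold].reset_index(drop=True)


def map_cpgs_to_res(
    cpg_ids,
    re_map: REMap,
    window_bp: int = DEFAULT_RE_WINDOW_BP,
    known_chroms: set[str] | None = None,
) -> dict[str, set[tuple[str, str]]]:
    """Map each CpG to the REs within ``window_bp`` of its position.

    A CpG maps to an RE iff the distance from the CpG to the nearest base
    of the interval is <= ``window_bp`` (0 inside; boundary inclusive).
    Returns cpg_id -> set of (re_id, target_gene).
    """
    if known_chroms is not None:
        for chrom, *_ in re_map.intervals:
            if chrom not in known_chroms:
                raise ValueError(f"unknown chromosome in RE map: {chrom!r}")
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end, rid in re_map.intervals:
        # interval bases are [start, end); a point p is within window_bp iff
        # start - window_bp <= p <= end - 1 + window_bp
        trees.setdefault(chrom, IntervalTree()).addi(
            start - window_bp, end + window_bp, (rid, re_map.re_targets.get(rid))
        )
    out: dict[str, set[tuple[str, str]]] = {}
    for ident in cpg_ids:
        chrom, pos = parse_cpg_id(ident)
        if known_chroms is not None and chrom not in known_chroms:
            raise ValueError(f"unknown chromosome in CpG input: {chrom!r}")
        tree = trees.get(chrom)
        hits = tree[pos] if tree is not None else set()
        out[ident] = {iv.data for iv in hits}
    return out


def genes_for_cpgs(cpg_to_res: dict[str, set[tuple[str, str]]]) -> set[str]:
    """Distinct target genes reachable from the mapped CpGs (gene-level dedup)."""
    return {gene for hits in cpg_to_res.values() for _, gene in hits if gene}


def enrich_go(
    target_genes: set[str],
    background_genes: set[str],
    gene_sets: dict[str, set[str]],
    restrict_to: set[str] | None = None,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment with BH correction.

    The universe is ``background_genes``; each term is intersected with it.
    ``restrict_to`` limits testing to a configured term list (e.g. the
    child terms of an immune-response parent).
    """
    extra = set(target_genes) - set(background_genes)
    if extra:
        raise ValueError(f"target genes not in background: {sorted(extra)}")
    if not gene_sets:
        raise ValueError("gene_sets is empty")
    terms = [t for t in gene_sets if restrict_to is None or t in restrict_to]
    N = len(background_genes)
    n = len(target_genes)
    rows = []
    for term in terms:
        members = gene_sets[term] & set(background_genes)
        K = len(members)
        k = len(members & set(target_genes))
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"term": term, "overlap": k, "term_size": K,
                     "target_size": n, "background_size": N, "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["adj_p"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
        df = df.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
    return df


def _matched_pairs(classes: list[str]) -> list[tuple[str, str]]:
    pairs = []
    for c in classes:
        if c.startswith("TIIC-"):
            suffix = c[len("TIIC-"):]
            partner = "PBMC-" + _PAIR_EQUIV.get(suffix, suffix)
            if partner in classes:
                pairs.append((c, partner))
    return pairs


def categorize_signature_dmcs(
    signature: SignatureMatrix,
    atlas: ReferenceAtlas,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    smoothing: bool = True,
) -> dict[str, set[str]]:
    """Count signature CpGs differential within each class-pair category.

    Categories: TIIC-PBMC (matched immune types across compartments),
    TIIC-TIIC and PBMC-PBMC (distinct immune types within a compartment).
    A CpG belongs to a category if significant for at least one of its
    pairs; categories are not mutually exclusive.
    """
    present = signature.cpg_ids[signature.cpg_ids.isin(atlas.cpg_ids)]
    if len(present) < len(signature.cpg_ids):
        raise ValueError("signature CpGs missing from the atlas")
    sub = atlas.subset_cpgs(present)
    classes = sub.classes()
    tiic = [c for c in classes if c.startswith("TIIC-")]
    pbmc = [c for c in classes if c.startswith("PBMC-")]

    pair_sets = {
        "TIIC-PBMC": _matched_pairs(classes),
        "TIIC-TIIC": [(a, b) for i, a in enumerate(tiic) for b in tiic[i + 1:]],
        "PBMC-PBMC": [(a, b) for i, a in enumerate(pbmc) for b in pbmc[i + 1:]],
    }
    out: dict[str, set[str]] = {}
    for category, pairs in pair_sets.items():
        hits: set[str] = set()
        for a, b in pairs:
            dmcs = call_dmcs(sub, a, b, p_threshold=p_threshold, smoothing=smoothing)
            hits |= set(dmcs["cpg_id"])
        out[category] = hits
    return out


@dataclass
class MarkerTestResult:
    gene: str
    n_dmcs: int
    statistic: float | None
    p_value: float | None
    mean_difference: float | None
    direction: str
    testable: bool
    reason: str = ""


def marker_hypomethylation_test(
    dmcs: pd.DataFrame,
    re_map: REMap,
    marker_genes: tuple[str, ...] = DC_ACTIVATION_MARKERS,
    window_bp: int = DEFAULT_RE_WINDOW_BP,
    min_dmcs: int = 3,
) -> list[MarkerTestResult]:
    """Paired t test of TIIC vs PBMC methylation at marker-proximal DMCs.

    ``dmcs`` must come from :func:`call_dmcs` between the tumor-infiltrating
    and blood DC classes (class_a = TIIC side, so mean_a - mean_b is the
    TIIC-PBMC difference).  Per marker gene, DMCs within ``window_bp`` of
    any RE targeting it are collected (IL12 expands to IL12A/IL12B) and the
    two group means are compared pairwise across those CpGs.  Markers with
    fewer than ``min_dmcs`` proximal DMCs are reported untestable.
    """
    mapping = map_cpgs_to_res(list(dmcs["cpg_id"]), re_map, window_bp=window_bp)
    results = []
    for marker in marker_genes:
        genes = MARKER_EXPANSION.get(marker, (marker,))
        known = [g for g in genes if re_map.res_targeting(g)]
        if not known:
            results.append(MarkerTestResult(marker, 0, None, None, None, "",
                                            False, "no REs target this gene"))
            continue
        rows = dmcs.loc[[
            any(gene in genes for _, gene in mapping[c]) for c in dmcs["cpg_id"]
        ]]
        if len(rows) < min_dmcs:
            results.append(MarkerTestResult(
                marker, len(rows), None, None, None, "", False,
                f"only {len(rows)} proximal DMCs (<{min_dmcs})"))
            continue
        t, p = stats.ttest_rel(rows["mean_a"], rows["mean_b"])
        diff = float((rows["mean_a"] - rows["mean_b"]).mean())
        results.append(MarkerTestResult(
            marker, len(rows), float(t), float(p), diff,
            "hypo-in-TIIC" if diff < 0 else "hyper-in-TIIC", True))
    return results
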