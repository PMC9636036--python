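"""Signature CpG selection and signature/mixture matrix assembly.

Signature CpGs are selected per cell-state class by a one-vs-rest Welch t
test on reference betas with Benjamini-Hochberg control across CpGs, an
absolute mean-difference floor, and a per-class cap; a CpG passing for
several classes is attributed to the class with the largest effect.  Three
reference modes are supported: the combined two-state panel (tiic+pbmc) and
the two single-state panels (tiic, pbmc); stromal classes (epithelial,
fibroblast) enter every mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import BulkMethylome, ReferenceAtlas, state_of_class

log = logging.getLogger(__name__)

MODES = ("tiic+pbmc", "tiic", "pbmc")

DEFAULT_FDR = 0.05
DEFAULT_MIN_DELTA_BETA = 0.2
DEFAULT_MAX_PER_CLASS = 200
RELAXED_PER_CLASS = 10  # sub-threshold CpGs kept per signal-free class with allow_relax


@dataclass
class SignatureMatrix:
    """Selected signature CpGs x cell-state classes."""

    values: pd.DataFrame  # CpG x class representative betas
    attribution: pd.Series  # CpG -> class it was selected for
    mode: str
    metadata: dict = field(default_factory=dict)

    @property
    def cpg_ids(self) -> pd.Index:
        return self.values.index

    @property
    def class_labels(self) -> list[str]:
        return list(self.values.columns)

    def counts_per_class(self) -> pd.Series:
        return self.attribution.value_counts().reindex(self.class_labels, fill_value=0)

    def subset(self, keep: pd.Index) -> "SignatureMatrix":
        return SignatureMatrix(
            values=self.values.loc[keep],
            attribution=self.attribution.loc[keep],
            mode=self.mode,
            metadata=dict(self.metadata),
        )


def _mode_classes(atlas: ReferenceAtlas, mode: str) -> list[str]:
    mode = mode.lower()
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    keep = []
    for c in atlas.classes():
        s = state_of_class(c)
        if s == "stromal":
            keep.append(c)
        elif mode == "tiic+pbmc":
            keep.append(c)
        elif mode == "tiic" and s == "TIIC":
            keep.append(c)
        elif mode == "pbmc" and s == "PBMC":
            keep.append(c)
    return keep


def select_signature_cpgs(
    atlas: ReferenceAtlas,
    mode: str = "tiic+pbmc",
    fdr_threshold: float = DEFAULT_FDR,
    min_delta_beta: float = DEFAULT_MIN_DELTA_BETA,
    max_per_class: int = DEFAULT_MAX_PER_CLASS,
    allow_relax: bool = False,
    representative: str = "median",
) -> SignatureMatrix:
    """One-vs-rest differential selection of signature CpGs.

    For each class in the chosen mode, betas of that class's replicates are
    compared against all other replicates per CpG (Welch t); p-values are
    BH-adjusted across CpGs; CpGs with FDR <= ``fdr_threshold`` and
    ``|mean difference| >= min_delta_beta`` are ranked by absolute effect
    and capped at ``max_per_class``.  Matrix entries are per-class medians
    (or means) of replicate betas at the selected CpGs.
    """
    if atlas.betas is None:
        raise ValueError("atlas has no beta matrix; run compute_beta first")
    classes = _mode_classes(atlas, mode)
    if len(classes) < 2:
        raise ValueError(f"mode {mode!r} leaves fewer than 2 classes")
    sub = atlas.subset_classes(classes)
    betas = sub.betas
    labels = sub.class_labels

    candidates: list[pd.DataFrame] = []
    for cls in classes:
        in_cls = (labels == cls).to_numpy()
        if in_cls.sum() < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 replicates")
        a = betas.loc[:, in_cls].to_numpy()
        b = betas.loc[:, ~in_cls].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
        delta = a.mean(axis=1) - b.mean(axis=1)
        p = np.where(np.isnan(p), 1.0, p)
        _, q, _, _ = multipletests(p, method="fdr_bh")
        ok = (q <= fdr_threshold) & (np.abs(delta) >= min_delta_beta)
        df = pd.DataFrame(
            {"cpg": betas.index, "cls": cls, "delta": delta, "q": q}
        )
        sel = df.loc[ok].reindex(
            df.loc[ok, "delta"].abs().sort_values(ascending=False).index
        )
        sel = sel.iloc[:max_per_class]
        if sel.empty:
            if not allow_relax:
                raise ValueError(
                    f"no CpG passed selection for class {cls!r} "
                    "(set allow_relax=True to keep its best sub-threshold CpGs)"
                )
            log.warning("class %s: no CpG passed; keeping best sub-threshold CpGs", cls)
            sel = df.reindex(
                df["delta"].abs().sort_values(ascending=False).index
            ).iloc[:RELAXED_PER_CLASS]
        candidates.append(sel)

    cand = pd.concat(candidates, ignore_index=True)
    # attribute multiply-selected CpGs to the class with the largest effect
    cand["absd"] = cand["delta"].abs()
    cand = cand.sort_values(["absd", "cls"], ascending=[False, True], kind="stable")
    attributed = cand.drop_duplicates("cpg", keep="first")
    missing = [c for c in classes if c not in set(attributed["cls"])]
    if missing:
        raise ValueError(
            f"classes with zero attributed signature CpGs: {missing} (no signal)"
        )

    sel_ids = atlas.cpg_ids[atlas.cpg_ids.isin(attributed["cpg"])]
    agg = np.median if representative == "median" else np.mean
    values = pd.DataFrame(
        {
            cls: agg(betas.loc[sel_ids, (labels == cls).to_numpy()].to_numpy(), axis=1)
            for cls in classes
        },
        index=sel_ids,
    )
    attribution = attributed.set_index("cpg")["cls"].reindex(sel_ids)
    sig = SignatureMatrix(
        values=values,
        attribution=attribution,
        mode=mode.lower(),
        metadata={
            "fdr_threshold": fdr_threshold,
            "min_delta_beta": min_delta_beta,
            "max_per_class": max_per_class,
            "representative": representative,
            "n_cpgs": int(len(sel_ids)),
            "counts_per_class": {
                c: int(n) for c, n in attribution.value_counts().items()
            },
        },
    )
    return sig


def build_mixture_matrix(
    bulk: BulkMethylome, signature: SignatureMatrix, min_present_fraction: float = 0.5
) -> tuple[pd.DataFrame, SignatureMatrix]:
    """Extract bulk betas at the signature CpGs, in signature order.

    Signature CpGs absent from the bulk universe are dropped from both
    sides (count logged); if fewer than ``min_present_fraction`` of the
    signature CpGs are present, the signature is inapplicable.
    """
    if bulk.betas is None:
        raise ValueError("bulk has no beta matrix")
    present = signature.cpg_ids.isin(bulk.cpg_ids)
    n_absent = int((~present).sum())
    if present.sum() < min_present_fraction * len(signature.cpg_ids):
        raise ValueError(
            f"only {int(present.sum())} of {len(signature.cpg_ids)} signature CpGs "
            f"present in bulk (<{min_present_fraction:.0%}); signature inapplicable"
        )
    if n_absent:
        log.warning("dropping %d signature CpGs absent from the bulk", n_absent)
    sig = signature.subset(signature.cpg_ids[present])
    mixture = bulk.betas.loc[sig.cpg_ids]
    return mixture, sig
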