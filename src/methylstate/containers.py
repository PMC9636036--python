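"""In-memory containers shared across the pipeline.

Methylation matrices are CpG x sample pandas DataFrames indexed by
"chrom:pos" identifiers (0-based positions, BED convention).  Beta values
live in [0, 1] with NaN marking sites removed by the depth filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STROMAL_STATE = "stromal"
TIIC_STATE = "TIIC"
PBMC_STATE = "PBMC"


def state_of_class(label: str) -> str:
    """Compartment tag of a cell-state class label.

    ``TIIC-*`` and ``PBMC-*`` labels carry their state as a prefix; anything
    else (epithelial, fibroblast) is stromal.
    """
    if label.startswith("TIIC-"):
        return TIIC_STATE
    if label.startswith("PBMC-"):
        return PBMC_STATE
    return STROMAL_STATE


@dataclass
class BulkMethylome:
    """Bulk-tumor methylome: the deconvolution "mixture" side.

    Parameters
    ----------
    betas
        CpG x sample beta values (may be None until :func:`compute_beta`).
    methylated, total
        Optional CpG x sample read-count matrices.
    """

    cpg_ids: pd.Index
    sample_ids: pd.Index
    betas: pd.DataFrame | None = None
    methylated: pd.DataFrame | None = None
    total: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.cpg_ids = pd.Index(self.cpg_ids)
        self.sample_ids = pd.Index(self.sample_ids)
        if self.cpg_ids.has_duplicates:
            raise ValueError("duplicate CpG identifiers")
        for m in (self.betas, self.methylated, self.total):
            if m is not None and m.shape != (len(self.cpg_ids), len(self.sample_ids)):
                raise ValueError("matrix shape does not match cpg_ids x sample_ids")
        if self.methylated is not None and self.total is not None:
            bad = (self.methylated.to_numpy() > self.total.to_numpy())
            if bad.any():
                i = int(np.argwhere(bad)[0, 0])
                raise ValueError(
                    f"methylated > total at CpG {self.cpg_ids[i]}"
                )

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_cpgs(self, keep: pd.Index) -> "BulkMethylome":
        keep = pd.Index(keep)
        return BulkMethylome(
            cpg_ids=keep,
            sample_ids=self.sample_ids,
            betas=None if self.betas is None else self.betas.loc[keep],
            methylated=None if self.methylated is None else self.methylated.loc[keep],
            total=None if self.total is None else self.total.loc[keep],
        )


@dataclass
class ReferenceAtlas(BulkMethylome):
    """Sorted-cell reference methylomes with per-sample class labels.

    ``class_labels`` maps each reference sample (column) to its cell-state
    class, e.g. ``TIIC-DC``; the compartment tag is derived from the label.
    """

    class_labels: pd.Series = field(default_factory=pd.Series)

    def __post_init__(self) -> None:
        super().__post_init__()
        self.class_labels = pd.Series(self.class_labels)
        if not self.class_labels.index.equals(self.sample_ids):
            self.class_labels = self.class_labels.reindex(self.sample_ids)
        if self.class_labels.isna().any():
            missing = self.sample_ids[self.class_labels.isna()].tolist()
            raise ValueError(f"samples without a class label: {missing}")
        if self.class_labels.nunique() < 2:
            raise ValueError("reference atlas needs at least 2 classes")

    @property
    def states(self) -> pd.Series:
        return self.class_labels.map(state_of_class)

    def classes(self) -> list[str]:
        seen: list[str] = []
        for c in self.class_labels:
            if c not in seen:
                seen.append(c)
        return seen

    def samples_of_class(self, label: str) -> pd.Index:
        return self.sample_ids[(self.class_labels == label).to_numpy()]

    def subset_cpgs(self, keep: pd.Index) -> "ReferenceAtlas":
        base = super().subset_cpgs(keep)
        return ReferenceAtlas(
            cpg_ids=base.cpg_ids,
            sample_ids=base.sample_ids,
            betas=base.betas,
            methylated=base.methylated,
            total=base.total,
            class_labels=self.class_labels,
        )

    def subset_classes(self, keep_classes: list[str]) -> "ReferenceAtlas":
        mask = self.class_labels.isin(keep_classes).to_numpy()
        cols = self.sample_ids[mask]
        return ReferenceAtlas(
            cpg_ids=self.cpg_ids,
            sample_ids=cols,
            betas=None if self.betas is None else self.betas[cols],
            methylated=None if self.methylated is None else self.methylated[cols],
            total=None if self.total is None else self.total[cols],
            class_labels=self.class_labels[cols],
        )


def cpg_id(chrom: str, pos: int) -> str:
    return f"{chrom}:{pos}"


def parse_cpg_id(ident: str) -> tuple[str, int]:
    chrom, pos = ident.rsplit(":", 1)
    return chrom, int(pos)
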