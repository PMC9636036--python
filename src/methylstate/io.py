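"""Plain-text readers and writers: TSV matrices, BED, GMT, JSON manifests."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import BulkMethylome, ReferenceAtlas, parse_cpg_id
from .deconvolution import CellProportionTable
from .signature import SignatureMatrix


def write_matrix_tsv(df: pd.DataFrame, path: str | Path, index_label: str = "cpg_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_matrix_tsv(path: str | Path, index_col: str = "cpg_id") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=index_col)
    df.index.name = None
    return df


def write_methylome(obj: BulkMethylome, prefix: str | Path) -> None:
    """Write betas/methylated/total matrices next to ``prefix``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if obj.betas is not None:
        write_matrix_tsv(obj.betas, f"{prefix}.betas.tsv")
    if obj.methylated is not None:
        write_matrix_tsv(obj.methylated, f"{prefix}.methylated.tsv")
    if obj.total is not None:
        write_matrix_tsv(obj.total, f"{prefix}.total.tsv")
    if isinstance(obj, ReferenceAtlas):
        obj.class_labels.rename("class").to_csv(
            f"{prefix}.classes.tsv", sep="\t", index_label="sample_id"
        )


def read_bulk(prefix: str | Path) -> BulkMethylome:
    prefix = Path(prefix)
    betas = meth = total = None
    if Path(f"{prefix}.betas.tsv").exists():
        betas = read_matrix_tsv(f"{prefix}.betas.tsv")
    if Path(f"{prefix}.methylated.tsv").exists():
        meth = read_matrix_tsv(f"{prefix}.methylated.tsv")
        total = read_matrix_tsv(f"{prefix}.total.tsv")
    ref = betas if betas is not None else meth
    if ref is None:
        raise FileNotFoundError(f"no matrices found at prefix {prefix}")
    return BulkMethylome(
        cpg_ids=ref.index, sample_ids=ref.columns, betas=betas,
        methylated=meth, total=total,
    )


def read_atlas(prefix: str | Path) -> ReferenceAtlas:
    bulk = read_bulk(prefix)
    labels = pd.read_csv(f"{prefix}.classes.tsv", sep="\t", index_col="sample_id")["class"]
    return ReferenceAtlas(
        cpg_ids=bulk.cpg_ids, sample_ids=bulk.sample_ids, betas=bulk.betas,
        methylated=bulk.methylated, total=bulk.total, class_labels=labels,
    )


def write_bed(intervals, path: str | Path) -> None:
    """6-column BED (0-based half-open) with the re_id in the name field."""
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t0\t.\n")


def read_bed(path: str | Path):
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append((f[0], int(f[1]), int(f[2]), f[3] if len(f) > 3 else ""))
    return out


def write_re_targets(re_targets: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("re_id\tgene\n")
        for rid, gene in re_targets.items():
            fh.write(f"{rid}\t{gene}\n")


def read_re_targets(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["re_id"], df["gene"]))


def write_gmt(gene_sets: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, genes in gene_sets.items():
            fh.write("\t".join([term, term] + sorted(genes)) + "\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    out = {}
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) >= 3:
                out[f[0]] = set(f[2:])
    return out


def write_cpg_bed(cpg_ids, path: str | Path) -> None:
    """CpG coordinates as BED3+name sidecar."""
    rows = []
    for ident in cpg_ids:
        chrom, pos = parse_cpg_id(ident)
        rows.append((chrom, pos, pos + 1, ident))
    write_bed(rows, path)


def write_signature(sig: SignatureMatrix, prefix: str | Path) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    table = sig.values.copy()
    table.insert(0, "attributed_class", sig.attribution)
    table.to_csv(f"{prefix}.tsv", sep="\t", index_label="cpg_id")
    with open(f"{prefix}.json", "w") as fh:
        json.dump({"mode": sig.mode, **sig.metadata}, fh, indent=2)


def read_signature(prefix: str | Path) -> SignatureMatrix:
    df = pd.read_csv(f"{prefix}.tsv", sep="\t", index_col="cpg_id")
    df.index.name = None
    with open(f"{prefix}.json") as fh:
        meta = json.load(fh)
    attribution = df.pop("attributed_class")
    return SignatureMatrix(values=df, attribution=attribution,
                           mode=meta.pop("mode"), metadata=meta)


def write_proportions(table: CellProportionTable, path: str | Path) -> None:
    out = pd.concat([table.proportions, table.diagnostics], axis=1)
    out.to_csv(path, sep="\t", index_label="sample_id")


def read_proportions(path: str | Path, class_labels: list[str]) -> CellProportionTable:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    diag_cols = [c for c in df.columns if c not in class_labels]
    return CellProportionTable(proportions=df[class_labels], diagnostics=df[diag_cols])


def write_clinical(clinical, path: str | Path) -> None:
    clinical.table.to_csv(path, sep="\t", index_label="sample_id")


def read_clinical(path: str | Path):
    from .recurrence import ClinicalTable

    return ClinicalTable(pd.read_csv(path, sep="\t", index_col="sample_id"))


class _JSONEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, pd.Series):
            return o.to_dict()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="index")
        return super().default(o)


def write_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, cls=_JSONEncoder)


def write_ground_truth(truth, path: str | Path) -> None:
    payload = {
        "planted_class_markers": {k: sorted(v) for k, v in truth.planted_class_markers.items()},
        "planted_state_dmcs": {k: sorted(v) for k, v in truth.planted_state_dmcs.items()},
        "label_model": truth.label_model,
    }
    if truth.true_proportions is not None:
        payload["true_proportions"] = truth.true_proportions.to_dict(orient="index")
    if truth.recurrence_probability is not None:
        payload["recurrence_probability"] = truth.recurrence_probability.to_dict()
    write_json(payload, path)
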