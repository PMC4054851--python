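"""Readers and writers for every on-disk artifact of the pipeline.

All tables are plain tab-delimited text with one header line (the dialect of
scanner-software exports such as GenePix result tables, without binding to a
vendor format). Every ``read_*``/``write_*`` pair round-trips exactly.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .model import (
    CALL_TOKENS,
    BisulfiteCloneSet,
    FormatError,
    NotISite,
    PanelSpec,
    QpcrSampleSet,
    SampleMeta,
    ValidationError,
)

SPOT_COLUMNS = ("clone_id", "replicate", "channel", "foreground", "background", "flag")
CHANNELS = ("tumor", "normal")
FLAGS = ("ok", "bad")


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")


# ---------------------------------------------------------------------------
# spot tables (one file per tumor/normal hybridization pair)

def read_spot_table(path) -> pd.DataFrame:
    """Read replicate spot intensities for one hybridization pair.

    Returns a DataFrame with columns ``clone_id, replicate, channel,
    foreground, background, flag``. Rows with foreground < background are
    accepted; net intensity clamps to zero downstream. Negative intensities
    are a row-level validation error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"clone_id": str})
    _require_columns(df, SPOT_COLUMNS, path)
    df = df.loc[:, list(SPOT_COLUMNS)]
    df["replicate"] = df["replicate"].astype(int)
    for col in ("foreground", "background"):
        df[col] = df[col].astype(float)
        bad = df.index[df[col] < 0]
        if len(bad):
            raise ValidationError(
                f"{path}: negative {col} at row(s) {list(bad[:5])}"
            )
    for col, allowed in (("channel", CHANNELS), ("flag", FLAGS)):
        unknown = set(df[col]) - set(allowed)
        if unknown:
            raise ValidationError(f"{path}: unknown {col} value(s) {sorted(unknown)}")
    if (df["replicate"] < 1).any():
        raise ValidationError(f"{path}: replicate indices must be >= 1")
    return df


def write_spot_table(spots: pd.DataFrame, path) -> None:
    spots.loc[:, list(SPOT_COLUMNS)].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# site and sample annotation tables

def read_sites(path) -> list[NotISite]:
    """Read NotI-site annotations (clone id, slash-separated genes, locus)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ("clone_id", "genes", "locus"), path)
    sites = []
    for row in df.itertuples(index=False):
        genes = tuple(g.strip() for g in str(row.genes).split("/") if g.strip())
        sites.append(NotISite(row.clone_id, genes, row.locus))
    ids = [s.clone_id for s in sites]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate clone_id in site table")
    return sites


def write_sites(sites: Iterable[NotISite], path) -> None:
    rows = [
        {"clone_id": s.clone_id, "genes": "/".join(s.gene_names), "locus": s.locus}
        for s in sites
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_samples(path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    _require_columns(df, ("sample_id", "histology", "stage"), path)
    return [
        SampleMeta(r.sample_id, r.histology, r.stage, getattr(r, "tnm", ""))
        for r in df.itertuples(index=False)
    ]


def write_samples(samples: Iterable[SampleMeta], path) -> None:
    rows = [
        {"sample_id": s.sample_id, "histology": s.histology, "stage": s.stage, "tnm": s.tnm}
        for s in samples
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# call matrices (sites x samples, tokens MD/AD/RET/NA)

def read_call_matrix(path) -> pd.DataFrame:
    """Read a sites x samples call matrix; cells are MD/AD/RET/NA tokens."""
    df = pd.read_csv(path, sep="\t", dtype=str, index_col=0, keep_default_na=False)
    df.index.name = "clone_id"
    unknown = set(np.unique(df.to_numpy())) - set(CALL_TOKENS)
    if unknown:
        raise FormatError(f"{path}: unknown call token(s) {sorted(unknown)}")
    return df


def write_call_matrix(matrix: pd.DataFrame, path) -> None:
    unknown = set(np.unique(matrix.to_numpy())) - set(CALL_TOKENS)
    if unknown:
        raise FormatError(f"refusing to write unknown call token(s) {sorted(unknown)}")
    matrix.to_csv(path, sep="\t", index_label="clone_id")


# ---------------------------------------------------------------------------
# marker panel definitions

def read_panel(path) -> PanelSpec:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    try:
        return PanelSpec(tuple(doc["markers"]), int(doc.get("k", 2)))
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{path}: panel file needs 'markers' list and optional 'k'") from exc


def write_panel(panel: PanelSpec, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"k": panel.k, "markers": list(panel.marker_clone_ids)}, fh)


# ---------------------------------------------------------------------------
# qPCR Ct tables (long format)

CT_COLUMNS = ("gene", "sample_id", "tissue", "assay", "replicate", "ct", "efficiency")


def write_ct_table(sets: Iterable[QpcrSampleSet], path) -> None:
    """Write QpcrSampleSets as a long table; assay is 'target' or the reference symbol."""
    rows = []
    for q in sets:
        blocks = [("target", q.e_tar, q.ct_tar_normal, q.ct_tar_tumor)] + [
            (r, q.e_ref[r], q.ct_ref_normal[r], q.ct_ref_tumor[r]) for r in q.references
        ]
        for assay, eff, normal, tumor in blocks:
            for tissue, cts in (("normal", normal), ("tumor", tumor)):
                for i, ct in enumerate(np.asarray(cts), start=1):
                    rows.append(
                        {"gene": q.gene, "sample_id": q.sample_id, "tissue": tissue,
                         "assay": assay, "replicate": i, "ct": float(ct), "efficiency": eff}
                    )
    pd.DataFrame(rows, columns=list(CT_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_ct_table(path) -> list[QpcrSampleSet]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, CT_COLUMNS, path)
    out: list[QpcrSampleSet] = []
    for (gene, sample), grp in df.groupby(["gene", "sample_id"], sort=False):
        def _cts(assay: str, tissue: str) -> np.ndarray:
            sel = grp[(grp["assay"] == assay) & (grp["tissue"] == tissue)]
            return sel.sort_values("replicate")["ct"].to_numpy()

        refs = sorted(set(grp["assay"]) - {"target"})
        if "target" not in set(grp["assay"]):
            raise FormatError(f"{path}: no target assay for {gene}/{sample}")
        eff = {a: float(grp.loc[grp["assay"] == a, "efficiency"].iloc[0]) for a in grp["assay"].unique()}
        out.append(
            QpcrSampleSet(
                gene=gene, sample_id=sample,
                ct_tar_normal=_cts("target", "normal"),
                ct_tar_tumor=_cts("target", "tumor"),
                ct_ref_normal={r: _cts(r, "normal") for r in refs},
                ct_ref_tumor={r: _cts(r, "tumor") for r in refs},
                e_tar=eff["target"], e_ref={r: eff[r] for r in refs},
            )
        )
    return out


# ---------------------------------------------------------------------------
# bisulfite clone matrices (clones x CpGs, 0/1), with '#key: value' metadata

def write_clone_matrix(cs: BisulfiteCloneSet, path) -> None:
    buf = _io.StringIO()
    buf.write(f"#gene: {cs.gene}\n#sample_id: {cs.sample_id}\n")
    buf.write("#noti_cpgs: " + ",".join(str(i) for i in cs.noti_cpg_indices) + "\n")
    header = ["clone"] + [f"cpg_{j:02d}" for j in range(1, cs.n_cpg + 1)]
    buf.write("\t".join(header) + "\n")
    for i, row in enumerate(cs.matrix.astype(int), start=1):
        buf.write(f"c{i:02d}\t" + "\t".join(map(str, row)) + "\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_clone_matrix(path) -> BisulfiteCloneSet:
    meta: dict[str, str] = {}
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
            body_start = i + 1
        else:
            break
    if "noti_cpgs" not in meta:
        raise FormatError(f"{path}: missing '#noti_cpgs:' metadata line")
    df = pd.read_csv(_io.StringIO("\n".join(lines[body_start:])), sep="\t", index_col=0)
    values = df.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise FormatError(f"{path}: clone matrix cells must be 0 or 1")
    return BisulfiteCloneSet(
        gene=meta.get("gene", ""),
        sample_id=meta.get("sample_id", ""),
        matrix=values.astype(bool),
        noti_cpg_indices=tuple(int(x) for x in meta["noti_cpgs"].split(",")),
    )


# ---------------------------------------------------------------------------
# run configuration

def load_config(path) -> dict:
    """Load a structured run configuration (YAML mapping)."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, Mapping):
        raise FormatError(f"{path}: run config must be a mapping")
    return dict(doc)


def dump_config(config: Mapping, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=True)
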