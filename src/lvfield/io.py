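"""Readers and writers for trait matrices, coordinates, trees and fields.

Trait matrices are accepted as wide CSV/TSV (header row of trait ids,
first column of sample ids) or as NEXUS files with a binary (0/1)
characters block.  Missing cells may be coded ``?``, ``-`` or left empty;
all three map to the same missing state.
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .containers import (
    MISSING_CODES,
    CoordinateTable,
    TraitMatrix,
    ValidationError,
    VelocityField,
)


class ParseError(ValueError):
    """Raised when a file cannot be parsed as the declared format."""


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in {".nex", ".nexus", ".nxs"}:
        return "nexus"
    if suffix == ".tsv":
        return "tsv"
    return "csv"


def _cell_to_state(raw, row: str, col: str) -> tuple[float, bool]:
    """Map a raw cell to (value, is_missing)."""
    text = "" if raw is None or (isinstance(raw, float) and np.isnan(raw)) else str(raw).strip()
    if text in MISSING_CODES:
        return 0.0, True
    if text in {"0", "0.0"}:
        return 0.0, False
    if text in {"1", "1.0"}:
        return 1.0, False
    raise ParseError(f"non-binary symbol {text!r} at sample {row!r}, trait {col!r}")


def read_trait_matrix(path: str | Path, format: str | None = None) -> TraitMatrix:
    """Read a binary trait matrix from CSV, TSV or NEXUS.

    1 codes presence of the trait (cognate) in the sample, 0 absence.
    """
    fmt = _infer_format(path, format)
    if fmt == "nexus":
        return _read_nexus_traits(path)
    if fmt not in {"csv", "tsv"}:
        raise ParseError(f"unknown trait-matrix format {fmt!r}")
    sep = "," if fmt == "csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    sample_ids = [str(s) for s in df.index]
    trait_ids = [str(t) for t in df.columns]
    values = np.zeros(df.shape)
    mask = np.zeros(df.shape, dtype=bool)
    arr = df.to_numpy()
    for i, sid in enumerate(sample_ids):
        for j, tid in enumerate(trait_ids):
            values[i, j], mask[i, j] = _cell_to_state(arr[i, j], sid, tid)
    return TraitMatrix(sample_ids, trait_ids, values, mask)


def _read_nexus_traits(path: str | Path) -> TraitMatrix:
    try:
        mat = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
    except Exception as exc:  # dendropy raises several error types
        raise ParseError(f"cannot parse NEXUS characters block in {path}: {exc}") from exc
    sample_ids = [t.label for t in mat.taxon_namespace]
    n = len(sample_ids)
    p = max(len(mat[t]) for t in mat.taxon_namespace)
    values = np.zeros((n, p))
    mask = np.zeros((n, p), dtype=bool)
    for i, taxon in enumerate(mat.taxon_namespace):
        seq = mat[taxon]
        if len(seq) != p:
            raise ParseError(f"ragged NEXUS matrix: sample {taxon.label!r}")
        for j, state in enumerate(seq):
            values[i, j], mask[i, j] = _cell_to_state(str(state), taxon.label, str(j))
    trait_ids = [f"t{j}" for j in range(p)]
    return TraitMatrix(sample_ids, trait_ids, values, mask)


def write_trait_matrix(tm: TraitMatrix, path: str | Path, format: str | None = None) -> None:
    fmt = _infer_format(path, format)
    if fmt == "nexus":
        lines = ["#NEXUS", "BEGIN DATA;", f"  DIMENSIONS NTAX={tm.n_samples} NCHAR={tm.n_traits};",
                 '  FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;', "  MATRIX"]
        for i, sid in enumerate(tm.sample_ids):
            row = "".join(
                "?" if tm.missing_mask[i, j] else str(int(tm.values[i, j]))
                for j in range(tm.n_traits)
            )
            lines.append(f"    '{sid}' {row}")
        lines += ["  ;", "END;", ""]
        Path(path).write_text("\n".join(lines))
        return
    sep = "," if fmt == "csv" else "\t"
    out = np.where(tm.missing_mask, "?", tm.values.astype(int).astype(str))
    df = pd.DataFrame(out, index=tm.sample_ids, columns=tm.trait_ids)
    df.to_csv(path, sep=sep)


def read_coordinates(path: str | Path, format: str | None = None) -> CoordinateTable:
    """Read an (id, lon, lat) table; ranges are validated on construction."""
    sep = "\t" if _infer_format(path, format) == "tsv" else ","
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    cols = {c.lower(): c for c in df.columns}
    try:
        idc, lonc, latc = cols["id"], cols["lon"], cols["lat"]
    except KeyError:
        if df.shape[1] < 3:
            raise ParseError(f"{path}: need columns id, lon, lat")
        idc, lonc, latc = df.columns[:3]
    ids = [str(s) for s in df[idc]]
    return CoordinateTable(ids, df[lonc].to_numpy(float), df[latc].to_numpy(float))


def write_coordinates(coords: CoordinateTable, path: str | Path) -> None:
    pd.DataFrame({"id": coords.sample_ids, "lon": coords.lon, "lat": coords.lat}).to_csv(
        path, index=False
    )


def read_newick(path: str | Path, sample_ids: list[str] | None = None) -> dendropy.Tree:
    """Read a Newick tree with branch lengths.

    If ``sample_ids`` is given, tip labels must match it exactly.
    """
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValidationError("tree edge without branch length")
    if sample_ids is not None:
        tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        extra, absent = sorted(tips - set(sample_ids)), sorted(set(sample_ids) - tips)
        if extra or absent:
            raise ValidationError(
                f"tip/sample mismatch: tips not in samples {extra}, samples not in tips {absent}"
            )
    return tree


def cophenetic_distances(tree: dendropy.Tree, sample_ids: list[str]) -> np.ndarray:
    """Pairwise patristic (branch-length) distances in sample order."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in set(sample_ids)}
    missing = [s for s in sample_ids if s not in taxa]
    if missing:
        raise ValidationError(f"samples not on tree: {missing}")
    n = len(sample_ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[sample_ids[i]], taxa[sample_ids[j]])
            out[i, j] = out[j, i] = d
    return out


def write_field(field: VelocityField, path: str | Path) -> None:
    """Write a velocity field as CSV (id, anchor_x, anchor_y, v_x, v_y)."""
    if field.n == 0:
        raise ValidationError("refusing to write an empty velocity field")
    if field.anchors.shape[1] != 2 or field.vectors.shape[1] != 2:
        raise ValidationError("write_field expects 2-D anchors and vectors")
    ids = field.ids if field.ids is not None else [str(i) for i in range(field.n)]
    pd.DataFrame(
        {
            "id": ids,
            "anchor_x": field.anchors[:, 0],
            "anchor_y": field.anchors[:, 1],
            "v_x": field.vectors[:, 0],
            "v_y": field.vectors[:, 1],
        }
    ).to_csv(path, index=False)


def read_field(path: str | Path, frame: str = "geo") -> VelocityField:
    df = pd.read_csv(path, dtype={"id": str})
    return VelocityField(
        frame,  # type: ignore[arg-type]
        df[["anchor_x", "anchor_y"]].to_numpy(float),
        df[["v_x", "v_y"]].to_numpy(float),
        ids=list(df["id"]),
    )
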