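"""Delimited-matrix dataset I/O.

The on-disk layout is a set of plain-text numeric matrices (TSV dialect by
default) tied together by a small YAML/JSON manifest naming the three
components of a disease-drug dataset: the binary association matrix
(diseases in rows, drugs in columns), the drug substructure-fingerprint bit
table, and a precomputed disease semantic-similarity matrix.  Everything is
read into dense double-precision arrays with explicit row/column
identifiers, and validated before any modelling code sees it.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "LabeledMatrix",
    "FingerprintSet",
    "DatasetBundle",
    "MatrixParseError",
    "BundleValidationError",
    "read_matrix",
    "write_matrix",
    "load_bundle",
    "write_bundle",
]


class MatrixParseError(ValueError):
    """Malformed delimited matrix file (ragged rows, non-numeric cells)."""


class BundleValidationError(ValueError):
    """A dataset bundle violates one of its structural invariants."""


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


@dataclass
class LabeledMatrix:
    """A dense numeric matrix with ordered, unique row and column ids."""

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        self.row_ids = [str(r) for r in self.row_ids]
        self.col_ids = [str(c) for c in self.col_ids]
        n, m = self.values.shape
        if len(self.row_ids) != n or len(self.col_ids) != m:
            raise ValueError(
                f"id counts ({len(self.row_ids)}, {len(self.col_ids)}) do not "
                f"match matrix shape {self.values.shape}"
            )
        if len(set(self.row_ids)) != n:
            raise ValueError("row ids are not unique")
        if len(set(self.col_ids)) != m:
            raise ValueError("column ids are not unique")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row_index(self, row_id: str) -> int:
        try:
            return self.row_ids.index(row_id)
        except ValueError:
            raise KeyError(f"unknown row id {row_id!r}") from None

    def reorder_columns(self, col_ids: list[str]) -> "LabeledMatrix":
        idx = [self.col_ids.index(c) for c in col_ids]
        return LabeledMatrix(self.values[:, idx], self.row_ids, list(col_ids))


@dataclass
class FingerprintSet:
    """Binary substructure fingerprints, one row per drug."""

    drug_ids: list[str]
    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.float64)
        if self.bits.ndim != 2:
            raise ValueError("bits must be a 2-D matrix")
        self.drug_ids = [str(d) for d in self.drug_ids]
        if len(self.drug_ids) != self.bits.shape[0]:
            raise ValueError("drug id count does not match bit-table rows")
        if len(set(self.drug_ids)) != len(self.drug_ids):
            raise ValueError("drug ids are not unique")
        if not np.isin(self.bits, (0.0, 1.0)).all():
            raise ValueError("fingerprint entries must be 0 or 1")


@dataclass
class DatasetBundle:
    """The full input set for one disease-drug prediction problem.

    ``associations`` is binary with diseases as rows and drugs as columns
    (the orientation every downstream module inherits).  ``fingerprints``
    covers a subset (normally all) of the association's drugs, and
    ``disease_semantic_sim`` is a square symmetric unit-diagonal matrix over
    exactly the association's diseases.
    """

    associations: LabeledMatrix
    fingerprints: FingerprintSet
    disease_semantic_sim: LabeledMatrix
    metadata: dict = field(default_factory=dict)

    SYM_TOL = 1e-8

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        O = self.associations.values
        if not np.isin(O, (0.0, 1.0)).all():
            bad = np.argwhere(~np.isin(O, (0.0, 1.0)))[0]
            raise BundleValidationError(
                f"association matrix is not binary (first offending cell "
                f"({bad[0]}, {bad[1]}) = {O[bad[0], bad[1]]!r})"
            )
        missing = set(self.fingerprints.drug_ids) - set(self.associations.col_ids)
        if missing:
            raise BundleValidationError(
                f"fingerprint drugs absent from association columns: "
                f"{sorted(missing)[:10]}"
            )
        if self.disease_semantic_sim.row_ids != self.associations.row_ids:
            raise BundleValidationError(
                "semantic-similarity diseases do not match association rows"
            )
        S = self.disease_semantic_sim.values
        if S.shape[0] != S.shape[1]:
            raise BundleValidationError("semantic similarity is not square")
        asym = np.abs(S - S.T).max() if S.size else 0.0
        if asym > self.SYM_TOL:
            raise BundleValidationError(
                f"semantic similarity asymmetric (max |S - S^T| = {asym:.3g})"
            )
        if S.size and np.abs(np.diag(S) - 1.0).max() > self.SYM_TOL:
            raise BundleValidationError("semantic similarity diagonal is not 1")

    @property
    def n_diseases(self) -> int:
        return self.associations.shape[0]

    @property
    def n_drugs(self) -> int:
        return self.associations.shape[1]


def read_matrix(
    path: str | os.PathLike,
    has_header: bool | None = None,
    delimiter: str | None = None,
) -> LabeledMatrix:
    """Read a delimited numeric matrix, with or without id headers.

    ``has_header=None`` auto-detects: a non-numeric first token means a
    header row of column ids is present and each data row starts with its
    row id.  Headerless files get generated ids ``r0..``/``c0..``.
    ``delimiter=None`` splits on any whitespace run (tabs included).
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw_lines = fh.read().splitlines()

    def split(line: str) -> list[str]:
        if delimiter is None:
            return line.split()
        return line.split(delimiter) if line else []

    lines = [(i + 1, split(ln)) for i, ln in enumerate(raw_lines)]
    # drop fully blank trailing lines
    while lines and not lines[-1][1]:
        lines.pop()

    if not lines:
        # empty file: only valid as an explicit headered 0x0 matrix
        if has_header is False:
            raise MatrixParseError(f"{path}: empty file")
        return LabeledMatrix(np.zeros((0, 0)), [], [])

    if has_header is None:
        first_tokens = lines[0][1]
        has_header = bool(first_tokens) and not _is_number(first_tokens[0])

    if has_header:
        col_ids = [str(t) for t in lines[0][1]]
        body = lines[1:]
        row_ids, rows = [], []
        for lineno, toks in body:
            if not toks:
                raise MatrixParseError(f"{path}:{lineno}: blank row inside matrix")
            if len(toks) != len(col_ids) + 1:
                raise MatrixParseError(
                    f"{path}:{lineno}: expected {len(col_ids) + 1} fields "
                    f"(row id + {len(col_ids)} values), got {len(toks)}"
                )
            row_ids.append(toks[0])
            rows.append(toks[1:])
        values = _parse_body(rows, [ln for ln, _ in body], path)
        if not body:
            values = np.zeros((0, len(col_ids)))
        return LabeledMatrix(values, row_ids, col_ids)

    width = len(lines[0][1])
    for lineno, toks in lines:
        if len(toks) != width:
            raise MatrixParseError(
                f"{path}:{lineno}: ragged row ({len(toks)} fields, expected {width})"
            )
    values = _parse_body([t for _, t in lines], [ln for ln, _ in lines], path)
    return LabeledMatrix(
        values,
        [f"r{i}" for i in range(values.shape[0])],
        [f"c{j}" for j in range(values.shape[1])],
    )


def _parse_body(rows: list[list[str]], linenos: list[int], path) -> np.ndarray:
    out = np.empty((len(rows), len(rows[0]) if rows else 0), dtype=np.float64)
    for i, toks in enumerate(rows):
        for j, tok in enumerate(toks):
            try:
                out[i, j] = float(tok)
            except ValueError:
                raise MatrixParseError(
                    f"{path}:{linenos[i]}: non-numeric cell {tok!r} at "
                    f"row {i}, column {j}"
                ) from None
    return out


def write_matrix(
    m: LabeledMatrix, path: str | os.PathLike, delimiter: str = "\t"
) -> None:
    """Write a labeled matrix as delimited text, full double precision.

    Ids must not contain the delimiter; values are printed with 17
    significant digits so a read/write round trip is bit-exact.
    """
    for ident in list(m.row_ids) + list(m.col_ids):
        if delimiter in ident or any(ch.isspace() for ch in ident):
            raise ValueError(f"id {ident!r} contains the delimiter or whitespace")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(delimiter.join(m.col_ids) + "\n")
        for rid, row in zip(m.row_ids, m.values):
            fh.write(rid + delimiter)
            fh.write(delimiter.join(f"{v:.17g}" for v in row))
            fh.write("\n")


def _read_manifest(path: str) -> tuple[dict, str]:
    if os.path.isdir(path):
        for name in ("bundle.yaml", "bundle.yml", "bundle.json", "manifest.yaml"):
            cand = os.path.join(path, name)
            if os.path.exists(cand):
                path = cand
                break
        else:
            raise FileNotFoundError(f"no bundle manifest found in directory {path!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(f"manifest file not found: {path!r}")
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    manifest = (
        json.loads(text) if path.endswith(".json") else yaml.safe_load(text)
    )
    if not isinstance(manifest, dict):
        raise BundleValidationError(f"manifest {path!r} is not a mapping")
    return manifest, os.path.dirname(os.path.abspath(path))


def load_bundle(path: str | os.PathLike) -> DatasetBundle:
    """Load and validate a dataset bundle from a manifest file or directory.

    The manifest names the three component files (paths relative to the
    manifest's directory)::

        associations: associations.tsv
        fingerprints: fingerprints.tsv
        disease_semantic_sim: disease_semantic_sim.tsv

    When the fingerprint drug-id set equals the association column-id set,
    association columns are reordered to the fingerprint order so the two
    components always agree positionally.
    """
    manifest, base = _read_manifest(str(path))
    required = ("associations", "fingerprints", "disease_semantic_sim")
    missing = [k for k in required if k not in manifest]
    if missing:
        raise BundleValidationError(f"manifest missing keys: {missing}")

    def resolve(p: str) -> str:
        return p if os.path.isabs(p) else os.path.join(base, p)

    assoc = read_matrix(resolve(manifest["associations"]))
    fp_m = read_matrix(resolve(manifest["fingerprints"]))
    sem = read_matrix(resolve(manifest["disease_semantic_sim"]))
    fps = FingerprintSet(fp_m.row_ids, fp_m.values)
    if set(fps.drug_ids) == set(assoc.col_ids) and fps.drug_ids != assoc.col_ids:
        assoc = assoc.reorder_columns(fps.drug_ids)
    metadata = dict(manifest.get("metadata", {}))
    return DatasetBundle(assoc, fps, sem, metadata)


def write_bundle(bundle: DatasetBundle, out_dir: str | os.PathLike) -> str:
    """Write a bundle as TSV components plus a ``bundle.yaml`` manifest.

    Returns the manifest path; ``load_bundle`` on it round-trips losslessly.
    """
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    write_matrix(bundle.associations, os.path.join(out_dir, "associations.tsv"))
    fp_m = LabeledMatrix(
        bundle.fingerprints.bits,
        bundle.fingerprints.drug_ids,
        [f"bit{j}" for j in range(bundle.fingerprints.bits.shape[1])],
    )
    write_matrix(fp_m, os.path.join(out_dir, "fingerprints.tsv"))
    write_matrix(
        bundle.disease_semantic_sim,
        os.path.join(out_dir, "disease_semantic_sim.tsv"),
    )
    manifest = {
        "associations": "associations.tsv",
        "fingerprints": "fingerprints.tsv",
        "disease_semantic_sim": "disease_semantic_sim.tsv",
        "metadata": bundle.metadata,
    }
    manifest_path = os.path.join(out_dir, "bundle.yaml")
    tmp = manifest_path + ".tmp"
    with open(tmp, "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh)
    os.replace(tmp, manifest_path)
    return manifest_path
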