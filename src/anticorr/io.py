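"""Readers and writers for expression matrices and pipeline outputs.

Canonical in-memory orientation is genes x cells. Supported formats:
MatrixMarket directories (``matrix.mtx`` + ``genes.tsv``/``features.tsv`` +
``barcodes.tsv``), dense TSV/CSV (gene ids in the first column, cell ids in
the header) and a simple self-describing HDF5 container with ``values``,
``gene_ids``, ``cell_ids`` datasets and a ``layer`` attribute.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


@dataclass
class AnnotatedMatrix:
    """Genes x cells matrix with identifiers and a provenance log."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    layer: str = "counts"
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if sparse.issparse(self.values):
            self.values = np.asarray(self.values.todense())
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows"
            )
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix columns"
            )
        self.gene_ids = _deduplicate(list(map(str, self.gene_ids)), self.log)
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("cell ids must be unique")


def _deduplicate(ids: list[str], log: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    n_dup = 0
    for g in ids:
        if g in seen:
            seen[g] += 1
            out.append(f"{g}.{seen[g]}")
            n_dup += 1
        else:
            seen[g] = 0
            out.append(g)
    if n_dup:
        log.append(f"disambiguated {n_dup} duplicate gene ids with .N suffixes")
    return out


def read_matrix(
    path: str | Path, fmt: str | None = None, cells_in_rows: bool = False
) -> AnnotatedMatrix:
    """Read an expression matrix; genes end up in rows.

    ``fmt`` one of ``mtx_dir``, ``tsv``, ``csv``, ``h5``; inferred from the
    path when omitted. ``cells_in_rows=True`` transposes tabular input.
    """
    path = Path(path)
    if fmt is None:
        if path.is_dir():
            fmt = "mtx_dir"
        elif path.suffix in (".h5", ".hdf5"):
            fmt = "h5"
        elif path.suffix == ".csv":
            fmt = "csv"
        else:
            fmt = "tsv"
    if fmt == "mtx_dir":
        am = _read_mtx_dir(path)
    elif fmt in ("tsv", "csv"):
        df = pd.read_csv(path, sep="," if fmt == "csv" else "\t", index_col=0,
                         comment="#")
        am = AnnotatedMatrix(
            values=df.to_numpy(dtype=np.float64),
            gene_ids=list(df.index.astype(str)),
            cell_ids=list(df.columns.astype(str)),
        )
    elif fmt == "h5":
        am = _read_h5(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if cells_in_rows:
        am = AnnotatedMatrix(
            values=am.values.T, gene_ids=am.cell_ids, cell_ids=am.gene_ids,
            layer=am.layer, log=am.log,
        )
    am.log.append(f"read {fmt} from {path}: {am.values.shape[0]} genes x "
                  f"{am.values.shape[1]} cells")
    return am


def _read_mtx_dir(path: Path) -> AnnotatedMatrix:
    mtx = path / "matrix.mtx"
    if not mtx.exists():
        raise FileNotFoundError(f"{path} does not contain matrix.mtx")
    genes_file = path / "genes.tsv"
    if not genes_file.exists():
        genes_file = path / "features.tsv"
    barcodes_file = path / "barcodes.tsv"
    if not genes_file.exists() or not barcodes_file.exists():
        raise FileNotFoundError(
            f"{path} must contain genes.tsv (or features.tsv) and barcodes.tsv"
        )
    values = np.asarray(spio.mmread(mtx).todense())
    genes = pd.read_csv(genes_file, sep="\t", header=None)[0].astype(str).tolist()
    barcodes = pd.read_csv(barcodes_file, sep="\t", header=None)[0].astype(str).tolist()
    if values.shape != (len(genes), len(barcodes)):
        raise ValueError(
            f"matrix.mtx is {values.shape} but found {len(genes)} genes and "
            f"{len(barcodes)} barcodes"
        )
    return AnnotatedMatrix(values=values, gene_ids=genes, cell_ids=barcodes)


def _read_h5(path: Path) -> AnnotatedMatrix:
    with h5py.File(path, "r") as f:
        values = f["values"][...]
        genes = [g.decode() if isinstance(g, bytes) else str(g)
                 for g in f["gene_ids"][...]]
        cells = [c.decode() if isinstance(c, bytes) else str(c)
                 for c in f["cell_ids"][...]]
        layer = f.attrs.get("layer", "counts")
    return AnnotatedMatrix(values=values, gene_ids=genes, cell_ids=cells,
                           layer=str(layer))


def write_matrix(am: AnnotatedMatrix, path: str | Path, fmt: str = "tsv") -> None:
    """Write a matrix as MTX directory, dense TSV/CSV, or HDF5 container."""
    path = Path(path)
    if fmt == "mtx_dir":
        path.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(path / "matrix.mtx", sparse.csr_matrix(am.values))
        pd.Series(am.gene_ids).to_csv(path / "genes.tsv", sep="\t",
                                      index=False, header=False)
        pd.Series(am.cell_ids).to_csv(path / "barcodes.tsv", sep="\t",
                                      index=False, header=False)
    elif fmt in ("tsv", "csv"):
        df = pd.DataFrame(am.values, index=am.gene_ids, columns=am.cell_ids)
        df.to_csv(path, sep="," if fmt == "csv" else "\t")
    elif fmt == "h5":
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=am.values)
            f.create_dataset("gene_ids",
                             data=np.array(am.gene_ids, dtype="S"))
            f.create_dataset("cell_ids",
                             data=np.array(am.cell_ids, dtype="S"))
            f.attrs["layer"] = am.layer
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _config_header(config: dict | None) -> str:
    if not config:
        return ""
    return "# config: " + json.dumps(config, sort_keys=True, default=str) + "\n"


def write_feature_table(table: pd.DataFrame, path: str | Path,
                        config: dict | None = None) -> None:
    """FeatureTable to TSV with the nine documented columns.

    The config (and seed) used for the run is echoed in a ``# config:``
    header comment that parses back with :func:`read_config_header`.
    """
    cols = ["t_i", "d_i", "fp_hat", "fdr_hat", "n_pos_partners",
            "in_A", "in_M", "selected"]
    out = table[cols].copy()
    out.insert(0, "gene", table.index)
    with open(path, "w") as fh:
        fh.write(_config_header(config))
        out.to_csv(fh, sep="\t", index=False)


def write_labels(labels: np.ndarray, cell_ids: list[str], path: str | Path,
                 config: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_config_header(config))
        pd.DataFrame({"cell": cell_ids, "cluster": labels}).to_csv(
            fh, sep="\t", index=False)


def write_tree(root, path: str | Path, config: dict | None = None) -> None:
    payload = {"config": config or {}, "tree": root.to_dict()}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_config_header(path: str | Path) -> dict | None:
    """Parse the ``# config:`` header comment written by the writers."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# config: "):
        return json.loads(first[len("# config: "):])
    return None
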