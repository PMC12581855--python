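"""Dataset container and on-disk I/O.

The universal input record is a spot-by-gene count matrix with 2-D spatial
coordinates per spot, optional ground-truth domain labels, and — for
multislice experiments — a slice identifier per spot.  On disk the native
format is ``h5ad`` (AnnData: matrix in ``X``, labels/slice in ``obs``,
coordinates in ``obsm["spatial"]``); a directory of CSV files (and
optionally an MTX counts matrix) is accepted as a portable fallback.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData, read_h5ad

if TYPE_CHECKING:  # pragma: no cover
    from .cluster import ClusterResult
    from .config import RunConfig

SPATIAL_KEY = "spatial"
LABEL_KEY = "domain"
SLICE_KEY = "slice_id"


@dataclass
class ExpressionDataset:
    """A spot x gene expression matrix with spatial coordinates.

    ``counts`` holds raw nonnegative counts unless ``normalized`` is set,
    in which case the values are taken as already processed.  ``labels``
    (ground-truth spatial domains) and ``slice_id`` are optional.
    """

    counts: np.ndarray
    coords: np.ndarray
    gene_names: list[str]
    spot_ids: list[str]
    labels: np.ndarray | None = None
    slice_id: np.ndarray | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if sp.issparse(self.counts):  # pragma: no cover - defensive
            self.counts = self.counts.toarray()
        self.coords = np.asarray(self.coords, dtype=np.float64)
        n = self.counts.shape[0]
        if self.coords.shape != (n, 2):
            raise ValueError(
                f"coords must be (n_spots, 2); counts has {n} rows but coords has shape {self.coords.shape}"
            )
        if len(self.gene_names) != self.counts.shape[1]:
            raise ValueError(
                f"gene_names length {len(self.gene_names)} != number of genes {self.counts.shape[1]}"
            )
        if len(self.spot_ids) != n:
            raise ValueError(f"spot_ids length {len(self.spot_ids)} != number of spots {n}")
        for name in ("labels", "slice_id"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v)
                if v.shape[0] != n:
                    raise ValueError(f"{name} length {v.shape[0]} != number of spots {n}")
                setattr(self, name, v)
        if len(set(self.gene_names)) != len(self.gene_names):
            raise ValueError("gene_names must be unique")
        if self.slice_id is None and len(set(self.spot_ids)) != len(self.spot_ids):
            raise ValueError("spot_ids must be unique within a slice")
        if not self.normalized and np.any(self.counts < 0):
            raise ValueError("raw counts must be nonnegative (set normalized=True for processed data)")

    # ------------------------------------------------------------------
    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def to_anndata(self) -> AnnData:
        obs = pd.DataFrame(index=pd.Index(self.spot_ids, name="spot_id"))
        if self.labels is not None:
            obs[LABEL_KEY] = pd.Categorical(np.asarray(self.labels).astype(str))
        if self.slice_id is not None:
            obs[SLICE_KEY] = pd.Categorical(np.asarray(self.slice_id).astype(str))
        adata = AnnData(
            X=np.asarray(self.counts),
            obs=obs,
            var=pd.DataFrame(index=pd.Index(self.gene_names, name="gene")),
        )
        adata.obsm[SPATIAL_KEY] = self.coords.copy()
        adata.uns["normalized"] = bool(self.normalized)
        return adata

    @classmethod
    def from_anndata(cls, adata: AnnData) -> "ExpressionDataset":
        X = adata.X
        if sp.issparse(X):
            X = X.toarray()
        X = np.asarray(X)
        if SPATIAL_KEY in adata.obsm:
            coords = np.asarray(adata.obsm[SPATIAL_KEY])[:, :2]
        elif {"x", "y"} <= set(adata.obs.columns):
            coords = adata.obs[["x", "y"]].to_numpy(dtype=float)
        else:
            raise ValueError("no spatial coordinates found (obsm['spatial'] or obs x/y columns)")
        labels = adata.obs[LABEL_KEY].to_numpy() if LABEL_KEY in adata.obs else None
        slice_id = adata.obs[SLICE_KEY].to_numpy() if SLICE_KEY in adata.obs else None
        return cls(
            counts=X,
            coords=coords,
            gene_names=[str(g) for g in adata.var_names],
            spot_ids=[str(s) for s in adata.obs_names],
            labels=labels,
            slice_id=slice_id,
            normalized=bool(adata.uns.get("normalized", False)),
        )


# ---------------------------------------------------------------------- I/O


def load_dataset(path: str | Path, format: str | None = None) -> ExpressionDataset:
    """Read an :class:`ExpressionDataset` from ``h5ad`` or a CSV directory.

    ``format`` is inferred from the path when omitted: an ``.h5ad`` file or
    a directory containing ``counts.csv`` (or ``matrix.mtx``) plus
    ``coords.csv`` and optionally ``labels.csv``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such dataset: {path}")
    if format is None:
        format = "csv_dir" if path.is_dir() else "h5ad"
    if format == "h5ad":
        return ExpressionDataset.from_anndata(read_h5ad(path))
    if format == "csv_dir":
        return _load_csv_dir(path)
    raise ValueError(f"unknown format {format!r} (expected 'h5ad' or 'csv_dir')")


def _load_csv_dir(path: Path) -> ExpressionDataset:
    coords_file = path / "coords.csv"
    if not coords_file.exists():
        raise FileNotFoundError(f"missing {coords_file}")
    coords_df = pd.read_csv(coords_file)
    spot_col = coords_df.columns[0]
    spot_ids = coords_df[spot_col].astype(str).tolist()
    coords = coords_df.iloc[:, 1:3].to_numpy(dtype=float)

    mtx = path / "matrix.mtx"
    if mtx.exists():
        counts = np.asarray(scipy.io.mmread(mtx).todense(), dtype=float)
        genes_file = path / "genes.csv"
        if genes_file.exists():
            gene_names = pd.read_csv(genes_file, header=None)[0].astype(str).tolist()
        else:
            gene_names = [f"gene_{i}" for i in range(counts.shape[1])]
    else:
        counts_file = path / "counts.csv"
        if not counts_file.exists():
            raise FileNotFoundError(f"missing {counts_file} (or matrix.mtx)")
        counts_df = pd.read_csv(counts_file, index_col=0)
        counts = counts_df.to_numpy(dtype=float)
        gene_names = [str(g) for g in counts_df.columns]

    if counts.shape[0] != coords.shape[0]:
        raise ValueError(
            f"row-count mismatch: counts has {counts.shape[0]} spots but coords has {coords.shape[0]}"
        )
    labels = None
    labels_file = path / "labels.csv"
    if labels_file.exists():
        lab_df = pd.read_csv(labels_file)
        labels = lab_df.iloc[:, -1].to_numpy()
        if labels.shape[0] != counts.shape[0]:
            raise ValueError(
                f"row-count mismatch: labels has {labels.shape[0]} rows but counts has {counts.shape[0]}"
            )
    return ExpressionDataset(
        counts=counts, coords=coords, gene_names=gene_names, spot_ids=spot_ids, labels=labels
    )


def save_dataset(dataset: ExpressionDataset, path: str | Path) -> None:
    """Write the dataset to ``h5ad``."""
    dataset.to_anndata().write_h5ad(Path(path))


def save_results(
    dataset: ExpressionDataset,
    result: "ClusterResult",
    path: str | Path,
    config: "RunConfig | None" = None,
) -> None:
    """Write clustering output: an ``h5ad`` plus a sidecar labels CSV.

    The h5ad holds raw and refined labels in ``obs``, the reduced embedding
    in ``obsm["X_embedding"]`` and the run configuration (including the
    seed) in ``uns["run_config"]``; the sidecar ``<stem>.labels.csv`` holds
    ``spot_id,label_raw,label_refined`` for toolchain-independent use.
    """
    n = dataset.n_spots
    if n == 0:
        raise ValueError("cannot save results for an empty dataset (0 spots)")
    if len(result.labels_raw) != n or len(result.labels_refined) != n:
        raise ValueError(
            f"label length {len(result.labels_raw)} does not match dataset with {n} spots"
        )
    path = Path(path)
    adata = dataset.to_anndata()
    adata.obs["label_raw"] = pd.Categorical(np.asarray(result.labels_raw).astype(str))
    adata.obs["label_refined"] = pd.Categorical(np.asarray(result.labels_refined).astype(str))
    adata.obsm["X_embedding"] = np.asarray(result.embedding)
    adata.uns["cluster_method"] = result.method
    adata.uns["n_clusters"] = int(result.n_clusters)
    if config is not None:
        adata.uns["run_config"] = json.dumps(config.to_dict())
    adata.write_h5ad(path)
    sidecar = path.parent / (path.stem + ".labels.csv")
    pd.DataFrame(
        {
            "spot_id": dataset.spot_ids,
            "label_raw": np.asarray(result.labels_raw),
            "label_refined": np.asarray(result.labels_refined),
        }
    ).to_csv(sidecar, index=False)


def load_results(path: str | Path) -> tuple[ExpressionDataset, pd.DataFrame, dict]:
    """Read back a results h5ad: dataset, label table and metadata."""
    adata = read_h5ad(Path(path))
    labels = pd.DataFrame(
        {
            "spot_id": adata.obs_names,
            "label_raw": adata.obs["label_raw"].to_numpy(),
            "label_refined": adata.obs["label_refined"].to_numpy(),
        }
    )
    meta: dict = {"cluster_method": adata.uns.get("cluster_method")}
    if "run_config" in adata.uns:
        meta["run_config"] = json.loads(adata.uns["run_config"])
    drop = adata.obs.drop(columns=["label_raw", "label_refined"])
    adata2 = AnnData(X=adata.X, obs=drop, var=adata.var.copy())
    adata2.obsm[SPATIAL_KEY] = adata.obsm[SPATIAL_KEY]
    adata2.uns["normalized"] = bool(adata.uns.get("normalized", False))
    return ExpressionDataset.from_anndata(adata2), labels, meta


def concatenate_datasets(slices: Sequence[ExpressionDataset]) -> ExpressionDataset:
    """Row-concatenate slices sharing a gene universe, tagging slice_id."""
    if len(slices) < 1:
        raise ValueError("need at least one slice")
    genes = slices[0].gene_names
    for i, s in enumerate(slices[1:], start=1):
        if s.gene_names != genes:
            raise ValueError(f"slice {i} gene_names differ from slice 0")
    counts = np.vstack([s.counts for s in slices])
    coords = np.vstack([s.coords for s in slices])
    spot_ids = [f"s{i}:{sid}" for i, s in enumerate(slices) for sid in s.spot_ids]
    slice_id = np.concatenate([np.full(s.n_spots, i) for i, s in enumerate(slices)])
    labels = None
    if all(s.labels is not None for s in slices):
        labels = np.concatenate([np.asarray(s.labels) for s in slices])
    return ExpressionDataset(
        counts=counts,
        coords=coords,
        gene_names=list(genes),
        spot_ids=spot_ids,
        labels=labels,
        slice_id=slice_id,
        normalized=slices[0].normalized,
    )
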