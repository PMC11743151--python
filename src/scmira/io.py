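"""Readers and writers for the supported on-disk formats.

Counts are accepted as dense delimiter-separated tables (genes in rows,
header of cell barcodes; .txt/.tsv, optionally gzipped) or as MatrixMarket
triplets (matrix.mtx + features + barcodes, optionally gzipped).  Multiple
files found under a data directory are merged on gene identifiers; a
gzipped-TSV cache of the cleaned matrix is written so repeated runs skip
re-cleaning.  Spatial positions come as a CSV of barcode,x,y.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .activity import ActivityMatrix
from .preprocess import CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_counts",
    "read_spatial_positions",
    "write_outputs",
    "read_activity_matrix",
    "CACHE_NAME",
]

CACHE_NAME = "cleaned_counts.tsv.gz"
_DENSE_SUFFIXES = {".txt", ".tsv"}


@dataclass
class RunConfig:
    """Options of one end-to-end run (mirrors the CLI surface)."""

    data_path: str
    dataset_name: str
    mode: str | None = None  # spatial | single_cell_total | single_cell_comparative
    species: str = "homo_sapiens"
    populations: tuple | None = None
    mirnas: list | None = None
    cpus: int = -1
    sample_size: int = 10_000
    activity_threshold: float = 1e-5
    min_reads: int | None = None
    top_k: int = 10
    seed: int = 0
    debug: bool = False

    def __post_init__(self):
        if self.mode == "single_cell_comparative" or self.populations:
            if not self.populations or len(self.populations) != 2:
                raise ValueError("comparative mode requires exactly two population strings")

    def infer_mode(self, has_positions: bool) -> str:
        """Mode inference: positions file => spatial; two population
        strings => comparative; otherwise total."""
        if self.mode:
            return self.mode
        if has_positions:
            return "spatial"
        if self.populations:
            return "single_cell_comparative"
        return "single_cell_total"


def _strip_gz(path: Path) -> Path:
    return path.with_suffix("") if path.suffix == ".gz" else path


def _read_dense(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    try:
        df = df.astype(np.float64)
    except ValueError as exc:
        raise ValueError(f"non-numeric entries in {path}: {exc}") from exc
    return df


def _read_mtx_triplet(mtx: Path) -> pd.DataFrame:
    folder = mtx.parent

    def find(stem_options):
        for stem in stem_options:
            for suffix in (".tsv", ".tsv.gz", ".txt", ".txt.gz", ".csv", ".csv.gz"):
                p = folder / f"{stem}{suffix}"
                if p.exists():
                    return p
        raise FileNotFoundError(
            f"no {stem_options[0]} file next to {mtx} (tried {stem_options})"
        )

    features = find(["features", "genes"])
    barcodes = find(["barcodes"])
    mat = scipy.io.mmread(mtx)
    feat = pd.read_csv(features, sep="\t", header=None)
    # 10x features files carry (id, symbol, type); use the symbol column
    gene_ids = feat.iloc[:, 1] if feat.shape[1] >= 2 else feat.iloc[:, 0]
    bc = pd.read_csv(barcodes, sep="\t", header=None).iloc[:, 0]
    if mat.shape != (len(gene_ids), len(bc)):
        raise ValueError(
            f"{mtx}: matrix shape {mat.shape} does not match "
            f"{len(gene_ids)} features x {len(bc)} barcodes"
        )
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=np.float64)
    return pd.DataFrame(dense, index=list(gene_ids), columns=list(bc))


def _merge(frames: list[pd.DataFrame]) -> pd.DataFrame:
    if len(frames) == 1:
        return frames[0]
    seen: set = set()
    renamed = []
    for i, df in enumerate(frames):
        collide = [c for c in df.columns if c in seen]
        if collide:
            logger.warning(
                "merge: %d colliding barcode(s) in file %d suffixed with -%d",
                len(collide), i, i,
            )
            df = df.rename(columns={c: f"{c}-{i}" for c in collide})
        seen.update(df.columns)
        renamed.append(df)
    merged = pd.concat(renamed, axis=1, join="outer").fillna(0.0)
    return merged


def read_counts(path, use_cache: bool = True) -> CountMatrix:
    """Read one file or every recognized counts file under a directory.

    A gzipped-TSV cache of the merged matrix is written next to the data
    (``cleaned_counts.tsv.gz``) and reused on subsequent calls.
    """
    path = Path(path)
    if path.is_dir():
        cache = path / CACHE_NAME
        if use_cache and cache.exists():
            logger.info("reading cached matrix %s", cache)
            return CountMatrix(counts=pd.read_csv(cache, sep="\t", index_col=0))
        files = sorted(
            p for p in path.iterdir()
            if _strip_gz(p).suffix in _DENSE_SUFFIXES | {".mtx"}
            and not p.name.startswith(CACHE_NAME.split(".")[0])
            and _strip_gz(p).stem not in ("features", "genes", "barcodes")
        )
        if not files:
            raise FileNotFoundError(f"no counts files with a recognized extension in {path}")
        frames = [_read_one(p) for p in files]
        merged = _merge(frames)
        if use_cache:
            merged.to_csv(cache, sep="\t", compression="gzip")
        return CountMatrix(counts=merged)
    return CountMatrix(counts=_read_one(path))


def _read_one(path: Path) -> pd.DataFrame:
    suffix = _strip_gz(path).suffix
    if suffix in _DENSE_SUFFIXES:
        return _read_dense(path)
    if suffix == ".mtx":
        return _read_mtx_triplet(path)
    raise ValueError(f"unrecognized counts file extension: {path}")


def read_spatial_positions(path, m: CountMatrix | None = None) -> pd.DataFrame:
    """Positions CSV (barcode,x,y) -> DataFrame indexed by barcode.

    Duplicate barcodes are an error; positions without counts are dropped
    with a warning when a matrix is supplied.
    """
    pos = pd.read_csv(path)
    if pos.shape[1] < 3:
        raise ValueError(f"{path}: expected columns barcode,x,y")
    pos = pos.set_index(pos.columns[0])
    pos.columns = ["x", "y"] + list(pos.columns[2:])
    if pos.index.has_duplicates:
        dups = list(pos.index[pos.index.duplicated()])
        raise ValueError(f"{path}: duplicate barcode(s) {dups[:5]}")
    if m is not None:
        missing = pos.index.difference(m.counts.columns)
        if len(missing):
            logger.warning("%d position barcode(s) have no counts; dropped", len(missing))
            pos = pos.loc[pos.index.intersection(m.counts.columns)]
    return pos[["x", "y"]]


def write_outputs(
    activity: ActivityMatrix,
    report: pd.DataFrame,
    out_dir,
    top_k: int = 10,
    make_plots: bool = True,
) -> dict:
    """Write the activity matrix (TSV), the ranked report (TSV + static
    HTML with links to per-miRNA plots) and plots for the top_k miRNAs."""
    from . import viz  # deferred: pulls in matplotlib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["activity"] = out_dir / "activity_matrix.tsv"
    activity.pvalues.to_csv(paths["activity"], sep="\t")
    paths["report"] = out_dir / "ranked_mirnas.tsv"
    report.to_csv(paths["report"], sep="\t", index=False)

    plot_links = {}
    if make_plots and top_k > 0:
        mode = report["mode"].iloc[0] if len(report) else "total"
        for mir in report["mirna"].head(top_k):
            safe = mir.replace("/", "_")
            fig_path = out_dir / f"{safe}.png"
            try:
                if mode == "spatial" and activity.coords is not None:
                    viz.activity_map(activity.coords, activity, mir, fig_path)
                elif mode == "comparative" and activity.population is not None:
                    viz.comparative_histograms(activity, None, mir, fig_path)
                elif activity.coords is not None:
                    viz.activity_map(activity.coords, activity, mir, fig_path)
                else:
                    viz.comparative_histograms(activity, None, mir, fig_path, split=False)
                plot_links[mir] = fig_path.name
            except Exception as exc:  # plots are artifacts, never fatal
                logger.warning("plot for %s failed: %s", mir, exc)

    paths["html"] = out_dir / "ranked_mirnas.html"
    _write_html(report, plot_links, paths["html"])
    return paths


def _write_html(report: pd.DataFrame, plot_links: dict, path: Path) -> None:
    rows = []
    for _, row in report.iterrows():
        mir = row["mirna"]
        name = f'<a href="{plot_links[mir]}">{mir}</a>' if mir in plot_links else mir
        cells = "".join(
            f"<td>{row[c]:.3g}</td>" if isinstance(row[c], float) else f"<td>{row[c]}</td>"
            for c in report.columns
            if c != "mirna"
        )
        rows.append(f"<tr><td>{name}</td>{cells}</tr>")
    header = "".join(f"<th>{c}</th>" for c in ["mirna"] + [c for c in report.columns if c != "mirna"])
    path.write_text(
        "<html><body><h1>Ranked miRNAs</h1><table border=1>"
        f"<tr>{header}</tr>{''.join(rows)}</table></body></html>"
    )


def read_activity_matrix(path) -> ActivityMatrix:
    """Re-read a written activity matrix TSV."""
    return ActivityMatrix(pvalues=pd.read_csv(path, sep="\t", index_col=0))
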