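"""Shared input/output helpers: Matrix-Market triplets, TSV writers and the
per-run manifest that makes every subcommand reproducible."""

from __future__ import annotations

import json
import logging
import sys
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
from scipy import io as spio
from scipy import sparse

from . import __version__
from .config import AnalysisConfig

__all__ = ["read_mtx_triplet", "write_table", "write_run_manifest", "setup_logging"]

logger = logging.getLogger("lineagescreen")


def read_mtx_triplet(matrix_path, rows_path, cols_path) -> pd.DataFrame:
    """Read a Matrix-Market coordinate matrix with line-aligned row/column
    label files into a labeled (dense) DataFrame; duplicate coordinate
    entries are summed, per the format's convention."""
    mat = spio.mmread(matrix_path)
    rows = [ln.strip() for ln in Path(rows_path).read_text().splitlines() if ln.strip()]
    cols = [ln.strip() for ln in Path(cols_path).read_text().splitlines() if ln.strip()]
    if sparse.issparse(mat):
        mat = mat.tocsr()  # sums duplicate (i, j) entries
        dense = mat.toarray()
    else:
        dense = mat
    if dense.shape != (len(rows), len(cols)):
        raise ValueError(
            f"matrix shape {dense.shape} does not match labels "
            f"({len(rows)} rows, {len(cols)} cols)"
        )
    return pd.DataFrame(dense, index=pd.Index(rows), columns=pd.Index(cols))


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def write_run_manifest(
    out_dir,
    command: str,
    inputs: dict,
    config: AnalysisConfig,
    seed: int | None = None,
) -> Path:
    """Write a machine-readable record of one run: inputs, effective config
    (and its hash), seed and package version."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "inputs": {k: str(v) for k, v in inputs.items()},
        "config": config.model_dump(),
        "config_hash": config.digest(),
        "seed": seed if seed is not None else config.seed,
    }
    path = out_dir / f"{command}.manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path


def setup_logging(level: str = "INFO", jsonl_path=None) -> None:
    """Human-readable log to stderr; optional JSON-lines log to file."""
    root = logging.getLogger("lineagescreen")
    root.setLevel(level.upper())
    root.handlers.clear()
    sh = logging.StreamHandler(sys.stderr)
    sh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root.addHandler(sh)
    if jsonl_path is not None:
        class _JsonFormatter(logging.Formatter):
            def format(self, record):
                return json.dumps(
                    {
                        "time": self.formatTime(record),
                        "level": record.levelname,
                        "name": record.name,
                        "message": record.getMessage(),
                    }
                )

        fh = logging.FileHandler(jsonl_path)
        fh.setFormatter(_JsonFormatter())
        root.addHandler(fh)
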