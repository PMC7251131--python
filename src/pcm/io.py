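"""Delimited-text input/output and run configuration.

Series travel as CSV (one column per variable, optional header and time
column), edge tables as TSV, and run configurations as JSON.  Parsing is
strict: ragged rows, non-numeric cells and missing values raise
:class:`ParseError` naming the offending line.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .crossmap import DEFAULT_DELAYS
from .errors import ParseError

__all__ = ["read_timeseries_csv", "write_timeseries_csv", "write_edge_table", "RunConfig"]

_EDGE_COLUMNS = [
    "source", "target", "rho_C", "rho_D", "gamma", "best_delays", "p", "q", "decision",
]


def _detect_delimiter(line: str) -> str:
    return "\t" if line.count("\t") >= line.count(",") and "\t" in line else ","


def read_timeseries_csv(
    path,
    delimiter: str | None = None,
    time_column: str | None = None,
) -> pd.DataFrame:
    """Read aligned series from delimited text.

    The delimiter is auto-detected among comma/tab unless forced.  A
    header row of non-numeric labels is recognised automatically; without
    one, columns are named V1..Vn.  ``time_column`` drops the named
    column after parsing.  Column order is preserved.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: file is empty")
    sep = delimiter or _detect_delimiter(lines[0])
    first = [c.strip() for c in lines[0].split(sep)]

    def _numeric(cell: str) -> bool:
        try:
            float(cell)
            return True
        except ValueError:
            return False

    has_header = not all(_numeric(c) for c in first)
    names = first if has_header else [f"V{i+1}" for i in range(len(first))]
    body = lines[1:] if has_header else lines
    ncol = len(names)
    rows = []
    for lineno, ln in enumerate(body, start=2 if has_header else 1):
        cells = [c.strip() for c in ln.split(sep)]
        if len(cells) != ncol:
            raise ParseError(
                f"{path}:{lineno}: ragged row has {len(cells)} cells, expected {ncol}"
            )
        vals = []
        for j, cell in enumerate(cells):
            try:
                v = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric cell {cell!r} in column {names[j]!r}"
                ) from None
            if not np.isfinite(v):
                raise ParseError(
                    f"{path}:{lineno}: missing/non-finite value in column {names[j]!r}"
                )
            vals.append(v)
        rows.append(vals)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    df = pd.DataFrame(rows, columns=names)
    if time_column is not None:
        if time_column not in df.columns:
            raise ParseError(f"{path}: no such time column {time_column!r}")
        df = df.drop(columns=[time_column])
    return df


def write_timeseries_csv(data: pd.DataFrame, path) -> None:
    """Write series as CSV at full float precision (round-trip exact)."""
    data.to_csv(path, index=False, float_format="%.17g")


def write_edge_table(edge_frame: pd.DataFrame, path) -> None:
    """Write an edge table as TSV with a stable column and row order."""
    df = edge_frame.copy()
    for col in _EDGE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[_EDGE_COLUMNS].sort_values(["source", "target"]).reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class RunConfig:
    """JSON-serialisable description of one CLI run."""

    input_path: str = ""
    variables: list[str] = field(default_factory=list)
    output_dir: str = "."
    log_level: str = "INFO"
    embed_dim: int = 4
    embed_lag: int = 1
    embed_auto: bool = False
    delays: list[int] = field(default_factory=lambda: list(DEFAULT_DELAYS))
    k: int | None = None
    exclusion: int = 0
    threshold: float = 0.5
    order: int = 1
    surrogates: int = 0
    seed: int = 0
    conditioning_strategy: str = "all"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        payload = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ParseError(f"unknown config fields: {sorted(unknown)}")
        return cls(**payload)

    def to_pcm_config(self):
        from .embedding import EmbeddingSpec
        from .model import PcmConfig

        return PcmConfig(
            embedding="auto" if self.embed_auto else EmbeddingSpec(self.embed_dim, self.embed_lag),
            delays=tuple(self.delays),
            k=self.k,
            exclusion=self.exclusion,
            threshold=self.threshold,
            order=self.order,
            surrogates=self.surrogates,
            seed=self.seed,
            conditioning_strategy=self.conditioning_strategy,
        )
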