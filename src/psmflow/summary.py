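"""Summary table: per-parameter, per-stage report rows with provenance."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import FormatError


def _fmt(value) -> str:
    if isinstance(value, str):
        return value
    if isinstance(value, (int,)) and not isinstance(value, bool):
        return str(value)
    return format(float(value), ".6g")


class SummaryTable:
    """Rows keyed by parameter name, columns keyed by stage.

    Each populated cell stores (formatted value, provenance id of the
    upstream operation that produced it).
    """

    def __init__(self):
        self._cells: dict[tuple[str, int], tuple[str, str]] = {}
        self._param_order: list[str] = []

    def set(self, parameter: str, stage: int, value, provenance: str) -> None:
        if parameter not in self._param_order:
            self._param_order.append(parameter)
        self._cells[(parameter, int(stage))] = (_fmt(value), provenance)

    def get(self, parameter: str, stage: int) -> str | None:
        cell = self._cells.get((parameter, int(stage)))
        return cell[0] if cell else None

    def provenance(self, parameter: str, stage: int) -> str | None:
        cell = self._cells.get((parameter, int(stage)))
        return cell[1] if cell else None

    @property
    def parameters(self) -> list[str]:
        return list(self._param_order)

    @property
    def stages(self) -> list[int]:
        return sorted({s for (_, s) in self._cells})

    def to_frame(self) -> pd.DataFrame:
        stages = self.stages
        data = {
            f"stage_{s}": [self.get(p, s) if self.get(p, s) is not None else "NA" for p in self._param_order]
            for s in stages
        }
        return pd.DataFrame(data, index=pd.Index(self._param_order, name="parameter"))

    def __eq__(self, other) -> bool:
        if not isinstance(other, SummaryTable):
            return NotImplemented
        return (
            self._param_order == other._param_order
            and {k: v[0] for k, v in self._cells.items()}
            == {k: v[0] for k, v in other._cells.items()}
        )


def write_summary_table(summary: SummaryTable, path) -> None:
    """TSV: one row per parameter, one column per stage; missing cells 'NA'."""
    summary.to_frame().to_csv(path, sep="\t")


def read_summary_table(path) -> SummaryTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col="parameter", dtype=str, keep_default_na=False)
    out = SummaryTable()
    for col in df.columns:
        if not col.startswith("stage_"):
            raise FormatError(f"unexpected summary column {col!r}")
        stage = int(col.split("_", 1)[1])
        for param, val in df[col].items():
            if val != "NA":
                out.set(param, stage, val, provenance="file")
    # preserve row order even for parameters with all-NA rows
    out._param_order = list(df.index)
    return out
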