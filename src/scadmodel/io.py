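"""Strict CSV/JSON readers and writers for model artefacts."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from scadmodel.costs import UtilityCatalogue
from scadmodel.lifetable import LifeTable
from scadmodel.markov import ModelOutputs

_DATA_DIR = Path(__file__).parent / "data"

#: packaged synthetic stand-ins for the national life table and EQ-5D
#: catalogue (real sources are licensed); regenerable from
#: :func:`scadmodel.synthetic.synthetic_life_table` /
#: :func:`scadmodel.synthetic.synthetic_utility_catalogue`.
PACKAGED_LIFE_TABLE = _DATA_DIR / "synthetic_life_table.csv"
PACKAGED_UTILITY_CATALOGUE = _DATA_DIR / "synthetic_utility_catalogue.csv"

_LIFE_TABLE_COLUMNS = ("sex", "age", "qx")
_UTILITY_COLUMNS = ("sex", "age_lo", "age_hi", "base_utility")


def _read_csv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for col in required:
        bad = df.index[df[col].isna()]
        if len(bad):
            raise ValueError(f"{path}: column {col!r} has missing values at row(s) "
                             f"{bad[:5].tolist()} (0-based, excluding header)")
    return df


def read_life_table(path: str | Path) -> LifeTable:
    """Load a (sex, age, qx) life table; contiguity and range checked."""
    return LifeTable(_read_csv(path, _LIFE_TABLE_COLUMNS))


def write_life_table(table: LifeTable, path: str | Path) -> None:
    table.table.to_csv(path, index=False)


def read_utility_catalogue(path: str | Path) -> UtilityCatalogue:
    df = _read_csv(path, _UTILITY_COLUMNS)
    return UtilityCatalogue.from_frame(df)


def write_utility_catalogue(cat: UtilityCatalogue, path: str | Path) -> None:
    cat.to_frame().to_csv(path, index=False)


def write_results(outputs: ModelOutputs | dict[int, ModelOutputs], path: str | Path) -> None:
    """Write model outputs as JSON and a tidy CSV next to it."""
    path = Path(path)
    if isinstance(outputs, ModelOutputs):
        payload = outputs.to_dict()
        frame = pd.DataFrame([payload])
    else:
        payload = {str(k): v.to_dict() for k, v in outputs.items()}
        frame = pd.DataFrame(
            [{"key": k, **v} for k, v in payload.items()]
        )
    path.write_text(json.dumps(payload, indent=2))
    frame.to_csv(path.with_suffix(".csv"), index=False)


def read_results(path: str | Path) -> ModelOutputs | dict[str, ModelOutputs]:
    payload = json.loads(Path(path).read_text())
    if set(ModelOutputs.field_names()).issubset(payload):
        return ModelOutputs.from_dict(payload)
    return {k: ModelOutputs.from_dict(v) for k, v in payload.items()}
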