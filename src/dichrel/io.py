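"""Readers, writers, run configuration and deterministic fixtures.

Response matrices travel as plain CSV: one header row of item identifiers,
one row per person, entries 0/1, no index column.  Item banks travel either
as JSON ``{"D": ..., "items": [{"item_id": ..., "a": ..., "b": ...}, ...]}``
or as CSV with columns ``item_id,a,b`` and the shared scaling constant in a
``# D=...`` header comment.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model_core import (
    DEFAULT_D,
    ItemBank,
    sample_item_parameters,
    sample_theta,
    simulate_responses,
)

__all__ = [
    "read_responses",
    "write_responses",
    "read_bank",
    "write_bank",
    "make_fixtures",
    "RunConfig",
]

#: 4 persons x 3 items worked example: alpha = 0.75 by hand computation.
TOY_ALPHA_MATRIX = np.array([[1, 1, 1], [1, 1, 0], [1, 0, 0], [0, 0, 0]], dtype=np.int8)


def read_responses(path: str | Path) -> np.ndarray:
    """Read an N x I binary response matrix from CSV (header row required)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty response file") from None
    if df.shape[0] < 1 or df.shape[1] < 1:
        raise ValueError(f"{path}: no data rows")
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax())
        raise ValueError(f"{path}: missing value in row {row}")
    values = df.to_numpy()
    bad = ~np.isin(values, (0, 1))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: non-binary entry {values[r, c]!r} at row {r}, "
            f"column {df.columns[c]!r}"
        )
    return values.astype(np.int8)


def write_responses(responses: np.ndarray, path: str | Path) -> None:
    """Write a binary response matrix to CSV with generated item-ID header."""
    x = np.asarray(responses)
    if x.ndim != 2 or not np.isin(x, (0, 1)).all():
        raise ValueError("responses must be a binary N x I matrix")
    cols = [f"item{i + 1}" for i in range(x.shape[1])]
    pd.DataFrame(x.astype(np.int8), columns=cols).to_csv(path, index=False)


def read_bank(path: str | Path) -> ItemBank:
    """Read an item bank from JSON or CSV; missing D defaults to 1.702."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        items = payload.get("items")
        if not items:
            raise ValueError(f"{path}: no items in bank")
        a = np.array([it["a"] for it in items], dtype=float)
        b = np.array([it["b"] for it in items], dtype=float)
        if "D" in payload:
            d = float(payload["D"])
        else:
            warnings.warn(f"{path}: no D field; using default {DEFAULT_D}", stacklevel=2)
            d = DEFAULT_D
    else:
        d = None
        with open(path) as fh:
            first = fh.readline().strip()
        skip = 0
        if first.startswith("#"):
            skip = 1
            if "D=" in first:
                d = float(first.split("D=")[1])
        df = pd.read_csv(path, skiprows=skip)
        if d is None:
            warnings.warn(f"{path}: no D header; using default {DEFAULT_D}", stacklevel=2)
            d = DEFAULT_D
        a = df["a"].to_numpy(dtype=float)
        b = df["b"].to_numpy(dtype=float)
    if np.any(a <= 0):
        raise ValueError(f"{path}: nonpositive discrimination in bank")
    return ItemBank(a=a, b=b, D=d)


def write_bank(bank: ItemBank, path: str | Path) -> None:
    """Write an item bank to JSON (.json) or CSV with a ``# D=`` header."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "D": bank.D,
            "items": [
                {"item_id": f"item{i + 1}", "a": float(a), "b": float(b)}
                for i, (a, b) in enumerate(zip(bank.a, bank.b))
            ],
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        with open(path, "w") as fh:
            fh.write(f"# D={bank.D}\n")
            fh.write("item_id,a,b\n")
            for i, (a, b) in enumerate(zip(bank.a, bank.b)):
                fh.write(f"item{i + 1},{float(a)!r},{float(b)!r}\n")


def make_fixtures(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Emit a small deterministic fixture suite into ``out_dir``.

    Writes a 15-item bank sampled from the standard generating distributions,
    an N = 500 response matrix simulated from it, and the 4 x 3 toy matrix
    whose alpha is 0.75 by hand computation.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    bank = sample_item_parameters(15, rng)
    theta = sample_theta(500, rng=rng)
    resp = simulate_responses(theta, bank, rng)
    paths = {
        "bank": out / "bank15.json",
        "responses": out / "responses500.csv",
        "toy_alpha": out / "toy_alpha.csv",
    }
    write_bank(bank, paths["bank"])
    write_responses(resp, paths["responses"])
    write_responses(TOY_ALPHA_MATRIX, paths["toy_alpha"])
    return paths


@dataclass(frozen=True)
class RunConfig:
    """Serializable run configuration for the study harnesses."""

    seed: int = 0
    study: str = "study2"
    correlations: tuple[float, ...] = (0.3, 0.5, 0.7, 0.9)
    items_per_construct: tuple[int, ...] = tuple(range(10, 75, 5))
    test_lengths: tuple[int, ...] = (15, 40, 65)
    sample_sizes: tuple[int, ...] = (100, 300, 500, 1000, 3000)
    n_persons: int = 500
    n_reps: int = 200
    coefficients: tuple[str, ...] = ("DATrue", "DQ", "DA", "alpha", "GLB", "omega", "CFA", "GY")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("correlations", "items_per_construct", "test_lengths",
                    "sample_sizes", "coefficients"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        data = {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(self).items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
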