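"""File formats: count CSVs, scenario files, chain/summary/manifest output.

Count files are CSV with header ``zygosity,y11,yd,y00`` and one row per
zygosity (``MZ`` and ``DZ``), matching the 3-cell exchangeable data
representation.  Scenario files are YAML or JSON mappings with keys
``pi, q_mz, q_dz, n_mz, n_dz, seed``.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import pandas as pd
import yaml

from .inference import Chain
from .model import TwinCounts
from .priors import PrevalenceStudy
from .simulate import SimScenario

__all__ = [
    "read_counts",
    "write_counts",
    "read_scenario",
    "parse_prevalence_spec",
    "write_chain_csv",
    "write_summary",
    "write_manifest",
]

_COLUMNS = ["zygosity", "y11", "yd", "y00"]


class CountFileError(ValueError):
    """Malformed counts file (message carries the offending line number)."""


def read_counts(path: str | Path) -> tuple[TwinCounts, TwinCounts]:
    """Read a counts CSV into (MZ, DZ) vectors.

    Requires exactly one MZ and one DZ row; raises :class:`CountFileError`
    with a line number for malformed or missing rows.
    """
    path = Path(path)
    found: dict[str, TwinCounts] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [c.strip().lower() for c in header] != _COLUMNS:
            raise CountFileError(
                f"{path}:1: expected header '{','.join(_COLUMNS)}', got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 4:
                raise CountFileError(f"{path}:{lineno}: expected 4 fields, got {len(row)}")
            zyg = row[0].strip().upper()
            if zyg not in ("MZ", "DZ"):
                raise CountFileError(f"{path}:{lineno}: zygosity must be MZ or DZ, got {row[0]!r}")
            if zyg in found:
                raise CountFileError(f"{path}:{lineno}: duplicate {zyg} row")
            try:
                found[zyg] = TwinCounts(int(row[1]), int(row[2]), int(row[3]))
            except ValueError as exc:
                raise CountFileError(f"{path}:{lineno}: {exc}") from exc
    for zyg in ("MZ", "DZ"):
        if zyg not in found:
            raise CountFileError(f"{path}: missing {zyg} row")
    return found["MZ"], found["DZ"]


def write_counts(path: str | Path, y_mz: TwinCounts, y_dz: TwinCounts) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        writer.writerow(["MZ", y_mz.y11, y_mz.yd, y_mz.y00])
        writer.writerow(["DZ", y_dz.y11, y_dz.yd, y_dz.y00])


def read_scenario(path: str | Path, seed: int | None = None) -> SimScenario:
    """Read a simulation scenario from YAML or JSON; ``seed`` overrides."""
    path = Path(path)
    with path.open() as fh:
        raw = yaml.safe_load(fh)  # JSON is a YAML subset
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: scenario file must contain a mapping")
    required = {"pi", "q_mz", "q_dz", "n_mz", "n_dz"}
    missing = required - raw.keys()
    if missing:
        raise ValueError(f"{path}: missing scenario keys {sorted(missing)}")
    if seed is None:
        if "seed" not in raw:
            raise ValueError(f"{path}: scenario needs a seed (in the file or via --seed)")
        seed = int(raw["seed"])
    return SimScenario(
        pi=float(raw["pi"]),
        q_mz=float(raw["q_mz"]),
        q_dz=float(raw["q_dz"]),
        n_mz=int(raw["n_mz"]),
        n_dz=int(raw["n_dz"]),
        seed=seed,
    )


def parse_prevalence_spec(spec: str) -> PrevalenceStudy:
    """Parse 'N_AFFECTED/N_TOTAL' (e.g. '1693/2524359')."""
    parts = spec.split("/")
    if len(parts) != 2:
        raise ValueError(f"prevalence study must be N_AFFECTED/N_TOTAL, got {spec!r}")
    return PrevalenceStudy(n_affected=int(parts[0]), n_total=int(parts[1]))


def write_chain_csv(path: str | Path, chain: Chain) -> None:
    df = pd.DataFrame(
        {
            "iteration": range(1, chain.n_iter + 1),
            "lambda": chain.lam,
            "mu_mz": chain.mu_mz,
            "mu_dz": chain.mu_dz,
        }
    )
    df.to_csv(path, index=False)


def write_summary(df: pd.DataFrame, csv_path: str | Path, json_path: str | Path) -> None:
    df.to_csv(csv_path)
    payload = {
        "hpd_mass": df.attrs.get("hpd_mass", 0.95),
        "quantities": {name: dict(row) for name, row in df.iterrows()},
    }
    with Path(json_path).open("w") as fh:
        json.dump(payload, fh, indent=2)


def write_manifest(path: str | Path, manifest: dict) -> None:
    with Path(path).open("w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
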