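"""Delimited-text VLE dataset container and I/O.

A :class:`VleDataset` holds isothermal T-P-x-y records for a fixed component
list.  The on-disk format is plain CSV with a small commented header:

    # cpaeos-vle
    # components: CO2,glycerol
    # units: T K, P bar, mole fractions
    # <free-form metadata lines: key: value>
    T,P,x_1,x_2,y_1,y_2,weight
    323.15,150.0,0.067,0.933,0.99997,2.28e-05,1.0

Blank fields mark unmeasured phases (liquid-only or vapor-only records).
Numbers round-trip at 12 significant digits.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["VleDataset", "DatasetFormatError"]

_MAGIC = "# cpaeos-vle"


class DatasetFormatError(ValueError):
    """Malformed dataset file (reported with the offending header/column)."""


@dataclass
class VleDataset:
    """Isothermal VLE records for one system.

    Parameters
    ----------
    components : tuple of str
        Component names; column order of the composition blocks.
    frame : pandas.DataFrame
        Columns ``T`` (K), ``P`` (bar), ``x_1..x_n``, ``y_1..y_n`` (NaN when
        the phase was not measured) and ``weight``.
    meta : dict
        Free-form metadata (source label, noise description, ...).
    """

    components: tuple[str, ...]
    frame: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.components)
        cols = ["T", "P"] + self.x_cols + self.y_cols
        missing = [c for c in cols if c not in self.frame.columns]
        if missing:
            raise DatasetFormatError(f"dataset missing columns: {missing}")
        if "weight" not in self.frame.columns:
            self.frame = self.frame.assign(weight=1.0)
        self.validate()

    @property
    def x_cols(self) -> list[str]:
        return [f"x_{i + 1}" for i in range(len(self.components))]

    @property
    def y_cols(self) -> list[str]:
        return [f"y_{i + 1}" for i in range(len(self.components))]

    def validate(self) -> None:
        f = self.frame
        if (f["P"] <= 0).any():
            raise DatasetFormatError("all pressures must be positive")
        has_x = ~f[self.x_cols].isna().any(axis=1)
        has_y = ~f[self.y_cols].isna().any(axis=1)
        if not (has_x | has_y).all():
            raise DatasetFormatError("every record needs at least one measured phase")
        for cols, has in ((self.x_cols, has_x), (self.y_cols, has_y)):
            sums = f.loc[has, cols].sum(axis=1)
            if ((sums - 1.0).abs() > 1e-6).any():
                bad = int((sums - 1.0).abs().idxmax())
                raise DatasetFormatError(
                    f"compositions must sum to 1 +/- 1e-6 (record {bad}: {sums.max():.8f})"
                )

    @property
    def has_liquid(self) -> bool:
        return bool((~self.frame[self.x_cols].isna().any(axis=1)).any())

    @property
    def has_vapor(self) -> bool:
        return bool((~self.frame[self.y_cols].isna().any(axis=1)).any())

    def __len__(self) -> int:
        return len(self.frame)

    # -- I/O ----------------------------------------------------------------

    def write(self, path: str | Path) -> None:
        buf = io.StringIO()
        buf.write(_MAGIC + "\n")
        buf.write(f"# components: {','.join(self.components)}\n")
        buf.write("# units: T K, P bar, mole fractions\n")
        for k, v in self.meta.items():
            buf.write(f"# {k}: {v}\n")
        cols = ["T", "P"] + self.x_cols + self.y_cols + ["weight"]
        self.frame[cols].to_csv(buf, index=False, float_format="%.12g")
        Path(path).write_text(buf.getvalue())

    @classmethod
    def read(cls, path: str | Path) -> "VleDataset":
        lines = Path(path).read_text().splitlines()
        if not lines or lines[0].strip() != _MAGIC:
            raise DatasetFormatError(
                f"{path}: not a cpaeos VLE dataset (missing '{_MAGIC}' header)"
            )
        meta: dict = {}
        components: tuple[str, ...] | None = None
        body_start = 0
        for i, line in enumerate(lines):
            if not line.startswith("#"):
                body_start = i
                break
            content = line.lstrip("#").strip()
            if ":" in content:
                key, _, val = content.partition(":")
                key = key.strip().lower()
                if key == "components":
                    components = tuple(s.strip() for s in val.split(","))
                elif key != "units":
                    meta[key.strip()] = val.strip()
        if components is None:
            raise DatasetFormatError(f"{path}: header line '# components: ...' missing")
        frame = pd.read_csv(io.StringIO("\n".join(lines[body_start:])))
        n = len(components)
        expected = {"T", "P"} | {f"x_{i+1}" for i in range(n)} | {f"y_{i+1}" for i in range(n)}
        missing = sorted(expected - set(frame.columns))
        if missing:
            raise DatasetFormatError(
                f"{path}: column(s) {missing} missing for {n} components "
                f"(found: {sorted(frame.columns)})"
            )
        return cls(components=components, frame=frame, meta=meta)
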