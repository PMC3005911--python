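"""Amino-acid property scales: polarity and exchangeability.

The bundled polarity scale is Grantham's (1974) polarity index (AAIndex
accession GRAR740102). The bundled exchangeability matrix is a SYNTHETIC
direction-sensitive stand-in derived from that polarity scale (see the
data-file header); supply an experimental matrix via ``exchangeability_path``
for real analyses. Lookups are direction-sensitive: EX(source -> dest).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io_model import AMINO_ACIDS

__all__ = ["RadicalityScales", "load_polarity", "load_exchangeability", "load_scales"]


def _data_path(name: str) -> Path:
    return Path(str(resources.files("aaflux").joinpath("data", name)))


def load_polarity(path: str | Path | None = None) -> dict[str, float]:
    """Load a 20-entry polarity table (amino_acid<TAB>value)."""
    if path is None:
        path = _data_path("grantham1974_polarity.tsv")
    values: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        aa, v = line.split("\t")
        values[aa] = float(v)
    missing = set(AMINO_ACIDS) - set(values)
    if missing:
        raise ConfigError(f"polarity scale {path}: missing amino acids {sorted(missing)}")
    return values


def load_exchangeability(path: str | Path | None = None) -> pd.DataFrame:
    """Load a 20x20 exchangeability matrix (rows=source, cols=dest).

    Every off-diagonal cell must be present and positive; a missing cell is
    a configuration error raised here (fail-fast), never at query time.
    """
    if path is None:
        path = _data_path("exchangeability_synthetic.tsv")
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    aas = list(AMINO_ACIDS)
    try:
        df = df.loc[aas, aas]
    except KeyError as exc:
        raise ConfigError(f"exchangeability matrix {path}: missing row/column {exc}") from exc
    off = ~np.eye(20, dtype=bool)
    vals = df.to_numpy(dtype=float)
    if np.isnan(vals[off]).any():
        bad = [
            (aas[i], aas[j])
            for i, j in zip(*np.nonzero(np.isnan(vals) & off))
        ]
        raise ConfigError(
            f"exchangeability matrix {path}: missing cells {bad[:5]}"
            + ("..." if len(bad) > 5 else "")
        )
    if (vals[off] <= 0).any():
        raise ConfigError(f"exchangeability matrix {path}: non-positive cells")
    return df


@dataclass
class RadicalityScales:
    """Bundle of the polarity scale and the exchangeability matrix."""

    polarity: dict[str, float]
    exchangeability: pd.DataFrame

    def ex(self, source: str, dest: str) -> float:
        return float(self.exchangeability.loc[source, dest])


def load_scales(
    polarity_path: str | Path | None = None,
    exchangeability_path: str | Path | None = None,
) -> RadicalityScales:
    return RadicalityScales(
        polarity=load_polarity(polarity_path),
        exchangeability=load_exchangeability(exchangeability_path),
    )
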