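"""Run configuration: validated key-value settings loaded from TOML."""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path

from .errors import ConfigError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Pipeline settings; unknown keys in a config file are rejected.

    ``polarity_scale`` / ``exchangeability_path``: None selects the bundled
    tables. ``ambiguous_weighting``: ``split`` (1/n per alternative for
    branch-resolved tallies) or ``exclude``. ``chi2_null``: ``ks``
    (expectation proportional to clade branch lengths) or ``equal``.
    """

    polarity_scale: str | None = None
    exchangeability_path: str | None = None
    ambiguous_weighting: str = "split"
    mpr_cap: int = 10_000
    chi2_null: str = "ks"
    fdr_levels: list[float] = field(default_factory=lambda: [0.01, 0.05])
    bonferroni_alpha: float = 0.01
    min_unambiguous: int = 2
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.ambiguous_weighting not in ("split", "exclude"):
            raise ConfigError(
                f"ambiguous_weighting must be 'split' or 'exclude', "
                f"got {self.ambiguous_weighting!r}"
            )
        if self.chi2_null not in ("ks", "equal"):
            raise ConfigError(f"chi2_null must be 'ks' or 'equal', got {self.chi2_null!r}")
        if self.mpr_cap < 1:
            raise ConfigError("mpr_cap must be positive")
        for q in self.fdr_levels:
            if not 0 < q < 1:
                raise ConfigError(f"FDR level {q} outside (0, 1)")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        data = tomllib.loads(Path(path).read_text())
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
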