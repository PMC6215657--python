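"""Run configuration: a serializable record of every knob of an analysis."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All parameters of a differential-regulation run.

    Serializes to/from YAML; every run logs its fully resolved config so an
    analysis can be replayed exactly.
    """

    method: str = "agrp"           # "agrp" or "grp"
    tau: float | None = None       # confidence cutoff, grp only
    pvalue_engine: str = "permutation"  # "permutation" or "asymptotic"
    B: int = 1000                  # permutation count
    seed: int | None = None
    alpha: float = 0.05
    bh: bool = True
    cv_cutoff: float | None = 0.05
    tumor_label: str = "tumor"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in {"agrp", "grp"}:
            raise ValueError(f"method must be 'agrp' or 'grp', got {self.method!r}")
        if self.method == "grp" and self.tau is None:
            raise ValueError("method='grp' requires a tau cutoff")
        if self.pvalue_engine not in {"permutation", "asymptotic", "exact"}:
            raise ValueError(f"unknown p-value engine {self.pvalue_engine!r}")

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        if isinstance(source, (str, Path)) and Path(source).exists():
            source = Path(source).read_text()
        data = yaml.safe_load(source) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
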