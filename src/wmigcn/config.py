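"""Flat key=value run configuration with schema validation.

Config files are plain text, one ``dotted.key = value`` per line, ``#``
comments allowed.  Command-line overrides take precedence over the file.
Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional

from .gcn import GCNConfig

#: key -> (type, default)
SCHEMA: dict[str, tuple[type, Any]] = {
    "mi.n_bins": (int, 16),
    "mi.zero_diagonal": (bool, False),
    "adjacency.variant": (str, "wmi"),
    "adjacency.normalize": (str, "dataset"),
    "gcn.n_layers": (int, 15),
    "gcn.hidden_channels": (int, 32),
    "gcn.filter_order": (int, 2),
    "gcn.dropout": (float, 0.2),
    "gcn.learning_rate": (float, 0.02),
    "gcn.epochs": (int, 600),
    "gcn.weight_decay": (float, 0.0005),
    "gcn.patience": (int, 10),
    "gcn.seed": (int, 0),
    "gcn.node_feature_length": (int, 1000),
    "eval.k_folds": (int, 4),
    "eval.min_class_fraction": (float, 0.02),
    "data.dir": (str, ""),
    "data.labels": (str, ""),
    "run.seed": (int, 0),
}

_CHOICES = {
    "adjacency.variant": {"wmi", "mi", "identity"},
    "adjacency.normalize": {"none", "spectral", "dataset"},
}


class ConfigError(ValueError):
    pass


def _coerce(key: str, raw: Any) -> Any:
    typ, _ = SCHEMA[key]
    if typ is bool and isinstance(raw, str):
        low = raw.strip().lower()
        if low in {"true", "1", "yes"}:
            return True
        if low in {"false", "0", "no"}:
            return False
        raise ConfigError(f"{key}: cannot parse {raw!r} as bool")
    try:
        value = typ(raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{key}: cannot parse {raw!r} as {typ.__name__}") from exc
    if key in _CHOICES and value not in _CHOICES[key]:
        raise ConfigError(f"{key}: {value!r} not in {sorted(_CHOICES[key])}")
    return value


@dataclass
class RunConfig:
    """Validated, merged configuration tree with provenance."""

    values: dict[str, Any] = field(default_factory=dict)
    source: Optional[str] = None

    def __post_init__(self) -> None:
        merged = {key: default for key, (_, default) in SCHEMA.items()}
        for key, raw in self.values.items():
            if key not in SCHEMA:
                raise ConfigError(f"unknown config key {key!r}")
            merged[key] = _coerce(key, raw)
        self.values = merged

    def __getitem__(self, key: str) -> Any:
        return self.values[key]

    def with_overrides(self, overrides: Mapping[str, Any]) -> "RunConfig":
        out = dict(self.values)
        for key, raw in overrides.items():
            if raw is None:
                continue
            if key not in SCHEMA:
                raise ConfigError(f"unknown config key {key!r}")
            out[key] = _coerce(key, raw)
        return RunConfig(values=out, source=self.source)

    def gcn_config(self) -> GCNConfig:
        return GCNConfig(
            n_layers=self["gcn.n_layers"],
            hidden_channels=self["gcn.hidden_channels"],
            filter_order=self["gcn.filter_order"],
            dropout=self["gcn.dropout"],
            learning_rate=self["gcn.learning_rate"],
            epochs=self["gcn.epochs"],
            weight_decay=self["gcn.weight_decay"],
            early_stopping_patience=self["gcn.patience"],
            seed=self["gcn.seed"],
            node_feature_length=self["gcn.node_feature_length"],
        )

    def dump(self) -> str:
        lines = [f"{k} = {v}" for k, v in sorted(self.values.items())]
        return "\n".join(lines) + "\n"

    @staticmethod
    def from_file(path: str | Path) -> "RunConfig":
        values: dict[str, Any] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
            key, raw = (part.strip() for part in line.split("=", 1))
            values[key] = raw
        return RunConfig(values=values, source=str(path))
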