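"""Run configuration: QC thresholds, detector settings, I/O options.

Configuration files are TOML with ``[qc]``, ``[detector]`` and
``[simulator]`` sections; every field falls back to the library default,
so a config file only needs the values it overrides.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from .qc_preprocess import QCThresholds
from .tfo_detector import DetectorConfig

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    qc: QCThresholds = field(default_factory=QCThresholds)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    simulator: dict[str, Any] = field(default_factory=dict)
    log_level: str = "INFO"

    def to_toml(self) -> str:
        """Serialize to a TOML document that round-trips through
        ``load_config`` to an equivalent RunConfig."""
        # top-level keys must precede any [section] header in TOML
        lines: list[str] = [f'log_level = "{self.log_level}"', ""]
        for section, obj in (("qc", self.qc), ("detector", self.detector)):
            lines.append(f"[{section}]")
            for f in dataclasses.fields(obj):
                v = getattr(obj, f.name)
                lines.append(f"{f.name} = {_toml_value(v)}")
            lines.append("")
        if self.simulator:
            lines.append("[simulator]")
            for k, v in self.simulator.items():
                lines.append(f"{k} = {_toml_value(v)}")
            lines.append("")
        return "\n".join(lines).rstrip("\n") + "\n"


def _toml_value(v: Any) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    return f'"{v}"'


def load_config(source: str | Path | None) -> RunConfig:
    """Load a RunConfig from a TOML file path (None → all defaults)."""
    if source is None:
        return RunConfig()
    doc = tomllib.loads(Path(source).read_text())
    qc = QCThresholds(**doc.get("qc", {}))
    det = DetectorConfig(**doc.get("detector", {}))
    return RunConfig(
        qc=qc,
        detector=det,
        simulator=doc.get("simulator", {}),
        log_level=doc.get("log_level", "INFO"),
    )
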