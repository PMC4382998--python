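"""Analysis configuration.

Defaults reproduce the published analysis settings: a 116 bp peak shift and
300 bp scanning window for occupancy calling; phred-scaled thresholds of 20
(regions) / 70 (per-element) for the Q-value FDR, 13 for the empirical FDR
and 1 for the log2 ratio; methylation-window tests over 10 consecutive CpGs
with at least 10 observations per library, reported at phred FDR >= 13 with
no log2 floor; up to 7 genomic and 14 consensus alignments per read; 100 N
spacers in the concatenated consensus index; a 2% unmethylated spike-in;
and 25-element blocks for the occupancy-vs-methylation moving average.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ParseError


@dataclass
class PipelineConfig:
    peak_shift: int = 116
    window_size: int = 300
    window_step: int | None = None  # None -> window_size // 2
    q_threshold_regions: float = 20.0
    q_threshold_elements: float = 70.0
    efdr_threshold: float = 13.0
    log2_threshold: float = 1.0
    meth_window_cpgs: int = 10
    meth_min_obs: int = 10
    meth_fdr_threshold: float = 13.0
    meth_log2_threshold: float = 0.0
    genome_max_alignments: int = 7
    consensus_max_alignments: int = 14
    consensus_max_mismatch_frac: float = 0.2
    consensus_spacer: int = 100
    spike_in_fraction: float = 0.02
    spike_in_contig: str = "spikein"
    moving_average_block: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if self.window_step is None:
            self.window_step = self.window_size // 2

    @property
    def step(self) -> int:
        return self.window_step if self.window_step else self.window_size // 2

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        return cls(**parse_keyvalue_file(path, cls))


def parse_keyvalue_file(path: str | Path, target_cls) -> dict:
    """Parse a flat ``key = value`` text file into kwargs for a dataclass.

    Blank lines and ``#`` comments are ignored; values are coerced to the
    annotated field type.  Unknown keys raise :class:`ParseError`.
    """
    fields = {f.name: f for f in dataclasses.fields(target_cls)}
    out: dict = {}
    path = Path(path)
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParseError(f"expected key=value, got {line!r}", str(path), lineno)
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in fields:
            raise ParseError(f"unknown configuration key {key!r}", str(path), lineno)
        out[key] = _coerce(value, fields[key])
    return out


def _coerce(value: str, fld: dataclasses.Field):
    ann = str(fld.type)
    if "," in value:  # tuple-valued field, e.g. per-family lists
        parts = [p.strip() for p in value.split(",") if p.strip()]
        return tuple(_scalar(p) for p in parts)
    if value.lower() in ("true", "false"):
        return value.lower() == "true"
    if value.lower() in ("none", ""):
        return None
    if "str" in ann and "int" not in ann and "float" not in ann:
        return value
    return _scalar(value)


def _scalar(value: str):
    try:
        return int(value)
    except ValueError:
        pass
    try:
        return float(value)
    except ValueError:
        return value
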