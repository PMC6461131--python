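"""Run reporting and validation arithmetic."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

from .errors import ConfigError


def false_positive_rate(discrepant_sites: int, compared_calls: int) -> float:
    """Conservative false-positive percentage of a validation comparison.

    Treats every unresolved discrepant site as an error in our own calls:
    100 x discrepant / compared (e.g. 6 discrepancies over 480 compared
    calls gives 1.25%).
    """
    if compared_calls < 1:
        raise ConfigError("compared_calls must be >= 1")
    if not 0 <= discrepant_sites <= compared_calls:
        raise ConfigError("discrepant_sites outside [0, compared_calls]")
    return 100.0 * discrepant_sites / compared_calls


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunReport:
    """Machine-readable record of one pipeline run.

    Every demotion or mask decision made anywhere in the run appears exactly
    once (collected from call summaries); per-stage read counts reconcile:
    reads in = reads out + reads removed at each stage.
    """

    tool: str = "oreomt"
    version: str = ""
    input_digests: dict[str, str] = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def add_input(self, label: str, path) -> None:
        self.input_digests[label] = file_digest(path)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)
            fh.write("\n")
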