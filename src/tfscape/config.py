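"""Analysis configuration: defaults, provenance and flat-file parsing.

The config format is a flat ``key = value`` text file; ``[section]``
headers are allowed for grouping and ignored when resolving keys.
Every default is individually overridable, and each carries a
provenance tag saying whether it restates a published constant of the
analysis being reproduced ("paper") or is this package's own declared
convention ("convention").
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any


#: provenance of each default: the analysis's published constant vs ours
PROVENANCE: dict[str, str] = {
    "flank": "paper",
    "bin_width": "convention",
    "class_cutoff": "paper",
    "pseudocount": "convention",
    "cooccur_window": "paper",
    "n_subsamples": "paper",
    "scan_threshold": "convention",
    "diff_threshold_fold": "paper",
    "kmeans_k_bound": "paper",
    "kmeans_k_diff": "paper",
    "spacing_anchor": "paper",
    "spacing_max_dist": "convention",
    "effective_genome_length": "convention",
    "seed": "convention",
}

_SPACING_ANCHORS = ("end_to_start", "start_to_start")


@dataclass
class AnalysisConfig:
    """All tunable parameters of the pipeline, with their defaults."""

    flank: int = 1000               # bp either side of summits
    bin_width: int = 50             # bp per profile bin
    class_cutoff: float = 1.0       # +/- log2 fold-change class boundary
    pseudocount: float = 1.0        # added to normalized tag totals
    cooccur_window: int = 50        # bp for motif pair co-occurrence
    n_subsamples: int = 1000        # bootstrap background draws
    scan_threshold: float = 0.8     # fraction of max PWM score
    diff_threshold_fold: float = 2.0  # "at least twofold"
    kmeans_k_bound: int = 7         # clusters for bound-gene expression
    kmeans_k_diff: int = 15         # clusters for differential genes
    spacing_anchor: str = "end_to_start"
    spacing_max_dist: int = 100     # bp spacing histogram half-width
    anchor_motif: str = "TEAD"      # spacing anchor motif name
    partner_motif: str = "AP1"      # spacing partner motif name
    effective_genome_length: int = 2_000_000_000
    seed: int = 0
    outdir: str = "tfscape_out"
    # input paths (filled by `simulate` or given by the user)
    genome: str = ""
    peaks: str = ""
    tags_a: str = ""
    tags_b: str = ""
    fg_footprints: str = ""
    bg_regions: str = ""
    expression: str = ""
    expression_meta: str = ""
    genes: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = ("flank", "bin_width", "class_cutoff", "cooccur_window",
                    "n_subsamples", "scan_threshold", "diff_threshold_fold",
                    "kmeans_k_bound", "kmeans_k_diff", "spacing_max_dist",
                    "effective_genome_length")
        for name in positive:
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"config field {name!r} must be positive, got {v}")
        if not 0 < self.scan_threshold <= 1:
            raise ValueError(
                f"config field 'scan_threshold' must be in (0, 1], "
                f"got {self.scan_threshold}"
            )
        if self.diff_threshold_fold <= 1:
            raise ValueError(
                f"config field 'diff_threshold_fold' must exceed 1, "
                f"got {self.diff_threshold_fold}"
            )
        if self.spacing_anchor not in _SPACING_ANCHORS:
            raise ValueError(
                f"config field 'spacing_anchor' must be one of "
                f"{_SPACING_ANCHORS}, got {self.spacing_anchor!r}"
            )

    # ----------------------------------------------------------------

    @classmethod
    def from_file(cls, path: str | Path, **overrides: Any) -> "AnalysisConfig":
        raw = parse_flat_config(path)
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "AnalysisConfig":
        types = {f.name: f.type for f in fields(cls)}
        kwargs: dict[str, Any] = {}
        for key, value in raw.items():
            if key not in types:
                raise ValueError(f"unknown config field {key!r}")
            kwargs[key] = _coerce(value, types[key], key)
        return cls(**kwargs)

    def to_dict(self) -> dict[str, Any]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def show_defaults(self) -> str:
        lines = []
        default = AnalysisConfig.__new__(AnalysisConfig)
        for f in fields(self):
            if f.name in PROVENANCE:
                lines.append(
                    f"{f.name} = {f.default}   # {PROVENANCE[f.name]}"
                )
        return "\n".join(lines)


def _coerce(value: Any, typ: Any, key: str) -> Any:
    if not isinstance(value, str):
        return value
    typ = str(typ)
    try:
        if "int" in typ:
            return int(value)
        if "float" in typ:
            return float(value)
    except ValueError as exc:
        raise ValueError(f"config field {key!r}: cannot parse {value!r}") from exc
    return value


def parse_flat_config(path: str | Path) -> dict[str, str]:
    """Parse ``key = value`` lines; ``[section]`` headers are grouping
    only; ``#`` starts a comment."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line or (line.startswith("[") and line.endswith("]")):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            out[key] = value
    return out
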