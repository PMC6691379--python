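"""Run configuration.

A flat ``key = value`` text file feeds :class:`AnalysisConfig`; CLI flags
override file values, and every run logs the fully resolved configuration
so results can be reproduced from the log alone.
"""

from __future__ import annotations

import dataclasses
import logging
import os

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class AnalysisConfig:
    """Tunable constants of the analysis chain.

    Defaults encode the study design: peaks are assigned to genes whose
    strand-oriented TSS window spans -2 kb upstream to +6 kb downstream;
    composite binding profiles use 10 bp bins over +/-400 bp; a factor is
    "occupying" a bin when its profile reaches 50% of its own maximum; the
    Wnt burden counts panel genes at cohort z >= 1.5 and stratifies
    patients at >= 7 such genes; differential expression uses a SAM-style
    permutation FDR at 0.05 with 100 permutations; fold-change summaries
    keep the top 20 genes.
    """

    tss_window: tuple[int, int] = (-2000, 6000)
    profile_halfwidth: int = 400
    profile_binwidth: int = 10
    occupancy_threshold_frac: float = 0.5
    z_threshold: float = 1.5
    burden_cutoff: int = 7
    sam_permutations: int = 100
    sam_fdr: float = 0.05
    top_n: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.tss_window
        if not lo < hi:
            raise ValueError(f"tss_window lower {lo} must be < upper {hi}")
        for name in ("profile_halfwidth", "profile_binwidth", "top_n"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.occupancy_threshold_frac <= 1:
            raise ValueError("occupancy_threshold_frac must be in (0, 1]")
        if not 0 < self.sam_fdr < 1:
            raise ValueError("sam_fdr must be in (0, 1)")


_INT_FIELDS = {"profile_halfwidth", "profile_binwidth", "burden_cutoff",
               "sam_permutations", "top_n", "seed"}


def load_config(path: str | os.PathLike) -> dict:
    """Parse a flat ``key = value`` config file into a dict."""
    values: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected 'key = value'")
            key, raw = (s.strip() for s in line.split("=", 1))
            if key == "tss_window":
                lo, hi = (int(v) for v in raw.split(","))
                values[key] = (lo, hi)
            elif key in _INT_FIELDS:
                values[key] = int(raw)
            else:
                values[key] = float(raw)
    return values


def resolve_config(config_path: str | os.PathLike | None = None,
                   **overrides) -> AnalysisConfig:
    """Build an AnalysisConfig from file plus overrides, logging the result."""
    values = load_config(config_path) if config_path else {}
    values.update({k: v for k, v in overrides.items() if v is not None})
    cfg = AnalysisConfig(**values)
    logger.info("resolved config: %s", dataclasses.asdict(cfg))
    return cfg
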