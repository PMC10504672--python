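"""Pipeline configuration: every numeric threshold of every stage.

Defaults are the method's standard values; anything overridden is
logged so a run record always states the thresholds it used.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger("ptascrub")

COVERAGE_CLASSES = ("15x", "30x")


@dataclass
class PipelineConfig:
    """All tunable thresholds, with the method's standard defaults.

    Parameters
    ----------
    coverage_class
        "15x" or "30x"; selects the depth- and VAF-thresholds appropriate
        for the sample's target genome coverage.
    """

    coverage_class: str = "30x"
    seed: int = 0

    # -- prefilter (SMuRF-style) ------------------------------------------
    min_qual: float = 100.0          # QUAL >= 100, inclusive
    min_mq: float = 55.0             # MQ > 55, strict
    min_depth_30x: int = 10
    min_depth_15x: int = 5
    min_gq_het: int = 99             # het SNVs: GQ < 99 removed
    min_gq_hom: int = 10             # hom-alt SNVs: GQ < 10 removed
    min_gq_indel: int = 99           # indels: GQ >= 99 required in test and control
    min_vaf_snv_15x: float = 0.2
    min_vaf_snv_30x: float = 0.3
    min_vaf_indel: float = 0.25

    # -- allelic imbalance -------------------------------------------------
    ai_window: int = 200_000         # bp around the candidate
    ai_min_hets: int = 10            # informative sites needed for a defined AI p
    ai_loess_degree: int = 2
    ai_baf_clamp: float = 0.001      # predicted BAF clamped to [clamp, 1-clamp]

    # -- linked read analysis ----------------------------------------------
    linkage_error_rate: float = 0.005
    linkage_phred_cap: float = 3000.0
    linkage_false_max: float = 100.0     # score < 100 -> false positive
    linkage_true_min: float = 1000.0     # score > 1000 -> true variant

    # -- random forest -----------------------------------------------------
    rf_n_trees: int = 500
    rf_mtry: int = 4
    rf_distance_cap: float = 1e7

    # -- cutoff calibration ------------------------------------------------
    pr_label_true_min: float = 1000.0    # linkage score >= 1000 -> likely true
    pr_label_false_max: float = 1.0      # linkage score < 1 -> likely artifact
    pr_min_best_value: float = 0.7
    cosine_cutoff_lo: float = 0.1
    cosine_cutoff_hi: float = 0.8
    cosine_cutoff_step: float = 0.025
    min_spectrum_mutations: int = 30

    # -- indel filtering ---------------------------------------------------
    indel_db_min_vaf: float = 0.15       # VAF > 0.15 collected into the database
    indel_min_individuals: int = 2
    homopolymer_min_run: int = 5

    # -- SV / CNV ----------------------------------------------------------
    bin_size: int = 1000
    coarse_bin_size: int = 100_000
    segmentation_gamma: float = 100.0
    pon_outlier_quantile: float = 0.01   # bottom and top 1% PON bins excluded
    centromere_margin: int = 1_000_000
    sample_p_max: float = 0.05
    pon_p_max: float = 0.2
    loh_daf_min: float = 0.45
    gain_mode_low: float = 1 / 3
    gain_mode_high: float = 2 / 3
    gain_mode_tol: float = 0.12
    mode_min_hets: int = 20
    mode_rel_density: float = 0.10       # minor modes below 10% of peak suppressed
    daf_snap_window: int = 200_000
    daf_snap_tol: float = 0.1
    dup_min_daf: float = 0.18
    dup_min_ratio: float = 2.5           # copy-number units, 2 = diploid
    del_min_daf: float = 0.40
    del_max_ratio: float = 1.5
    max_bnd_coverage_15x: float = 100.0  # per-1-kb count at a breakend, 15x class
    min_inversion_size: int = 1000
    ctx_rescue_distance: int = 100_000
    bnd_pon_window: int = 2000

    _overrides: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.coverage_class not in COVERAGE_CLASSES:
            raise ValueError(
                f"coverage_class must be one of {COVERAGE_CLASSES}, "
                f"got {self.coverage_class!r}"
            )

    # depth / VAF thresholds resolved for the configured coverage class
    @property
    def min_depth(self) -> int:
        return self.min_depth_15x if self.coverage_class == "15x" else self.min_depth_30x

    @property
    def min_vaf_snv(self) -> float:
        return self.min_vaf_snv_15x if self.coverage_class == "15x" else self.min_vaf_snv_30x

    def replace(self, **kwargs) -> "PipelineConfig":
        """Return a copy with overrides applied; each override is logged."""
        for key, value in kwargs.items():
            default = getattr(type(self)(), key, None)
            if value != default:
                logger.info("config override: %s = %r (default %r)", key, value, default)
        cfg = dataclasses.replace(self, **kwargs)
        cfg._overrides = {**self._overrides, **kwargs}
        return cfg

    # -- flat key=value config file ---------------------------------------
    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Read a config from a flat ``key = value`` text file."""
        fields = {f.name: f.type for f in dataclasses.fields(cls) if not f.name.startswith("_")}
        kwargs: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            current = getattr(cls(), key)
            if isinstance(current, bool):
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                kwargs[key] = int(value)
            elif isinstance(current, float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls().replace(**kwargs)

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            if f.name.startswith("_"):
                continue
            lines.append(f"{f.name} = {getattr(self, f.name)}")
        Path(path).write_text("\n".join(lines) + "\n")
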