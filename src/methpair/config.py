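"""Configuration objects for simulation and the end-to-end pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict


import yaml

DEFAULT_CHROM_LENGTHS = {f"chr{i}": 10_000_000 for i in range(1, 23)}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic paired-tissue methylation study.

    Defaults mirror the study design being emulated: 120 individuals with
    one brain (prefrontal cortex) and one buccal sample each, processed in
    two laboratory batches of 44 and 76; a minority of CpGs with planted
    cross-tissue correlation, mostly positive; cell-mixture, batch,
    diagnosis, array and bisulfite-conversion covariate effects; and
    cis-acting genetic effects enriched among the correlated CpGs.
    All additive effects act on the logit (M-value) scale.
    """

    n_pairs: int = 120
    n_cpgs: int = 5000
    n_snps: int = 1000
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS)
    )
    frac_correlated: float = 0.05
    frac_negative: float = 0.014
    rho_target_range: tuple[float, float] = (0.3, 0.9)
    frac_mqtl: float = 0.15
    mqtl_enrichment: float = 4.0
    mqtl_effect_size: float = 1.0
    n_celltypes: dict[str, int] = field(
        default_factory=lambda: {"brain": 2, "buccal": 3}
    )
    dirichlet_alpha: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {"brain": (8.0, 4.0), "buccal": (6.0, 2.0, 2.0)}
    )
    batch_sizes: tuple[int, int] = (44, 76)
    covariate_effect_sds: dict[str, float] = field(
        default_factory=lambda: {
            "batch": 0.1,
            "diagnosis": 0.05,
            "array_id": 0.05,
            "array_position": 0.03,
            "conversion": 0.002,
            "celltype": 1.0,
        }
    )
    batch_effect_mean: float = 0.0
    shared_covariate_effects: bool = False
    frac_cell_informative: float = 0.10
    frac_flagged: dict[str, float] = field(
        default_factory=lambda: {"flag_xy": 0.02, "flag_snp": 0.02, "flag_multimap": 0.01}
    )
    noise_sd: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self):
        for name in ("frac_correlated", "frac_negative", "frac_mqtl", "frac_cell_informative"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if sum(self.batch_sizes) != self.n_pairs:
            raise ValueError(
                f"batch_sizes {self.batch_sizes} must sum to n_pairs={self.n_pairs}"
            )
        lo, hi = self.rho_target_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("rho_target_range must be a sub-interval of (0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be a sub-interval of (0, 0.5]")
        if not self.chrom_lengths:
            raise ValueError("chrom_lengths must be non-empty")
        for tissue, k in self.n_celltypes.items():
            alpha = self.dirichlet_alpha.get(tissue)
            if alpha is None or len(alpha) != k:
                raise ValueError(
                    f"dirichlet_alpha for tissue {tissue!r} must have length {k}"
                )

    @property
    def tissues(self) -> tuple[str, ...]:
        return tuple(self.n_celltypes)

    @property
    def batches(self) -> tuple[str, str]:
        return ("batch1", "batch2")


@dataclass
class PipelineConfig:
    """Resolved parameters for an end-to-end run. Thresholds default to the
    values of the analysis being reproduced."""

    out_dir: str = "methpair_out"
    seed: int = 0
    # stage thresholds
    conversion_threshold: float = 80.0
    outlier_threshold: float = 0.15
    detection_p: float = 0.01
    min_beads: int = 3
    max_bead_fail_frac: float = 0.05
    bin_size: int = 100_000
    alpha: float = 0.01
    pc_method: str = "cumvar"
    pc_param: float = 0.8
    direct_pc_k: int = 3
    q_thresh: float = 0.05
    rho_thresh: float = 0.5
    batch_p_thresh: float = 0.05
    cis_window: int = 1_000_000
    mqtl_report_p: float = 0.05
    n_dnam_pcs_mqtl: int = 10
    yates: bool = True
    run_mqtl: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim_raw = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim_raw is not None:
            sim_known = {f.name for f in fields(SimulationConfig)}
            sim_unknown = set(sim_raw) - sim_known
            if sim_unknown:
                raise ValueError(f"unknown simulation config keys: {sorted(sim_unknown)}")
            for key in ("rho_target_range", "maf_range", "batch_sizes"):
                if key in sim_raw:
                    sim_raw[key] = tuple(sim_raw[key])
            if "dirichlet_alpha" in sim_raw:
                sim_raw["dirichlet_alpha"] = {
                    k: tuple(v) for k, v in sim_raw["dirichlet_alpha"].items()
                }
            cfg.simulation = SimulationConfig(**sim_raw)
        return cfg

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
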