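"""Simulation configuration for the synthetic aneuploid-genome testbed.

The generator emulates a male Drosophila S2-like cell line: a tetraploid
genome (autosomes at four copies, X at two) carrying large segmental
aneuploidies, Poisson windowed DNA read counts at a fixed per-copy density,
and gene expression that combines a saturating dose response with an
X-specific fixed-fold MSL multiplier.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import yaml

#: RPKM contributed by a single genomic copy in 1 kb DNA windows.
DEFAULT_PER_COPY_RPKM = 2.29
#: Fixed-fold boost of X-linked expression attributable to the MSL complex.
DEFAULT_MSL_MULTIPLIER = 1.35
#: Scaled dose at which expression is half-maximal in y = x(E+1)/(E+x).
DEFAULT_EC50 = 2.0


@dataclass(frozen=True)
class ArmSpec:
    """One chromosome arm: name, length in kb, X flag, optional gene count."""

    name: str
    length_kb: int
    is_x: bool = False
    n_genes: int | None = None


def default_arm_specs() -> list[ArmSpec]:
    """Scaled-down five-arm genome (four autosomal arms plus X).

    Arm lengths are far below the real ~23 Mb Drosophila arms so the
    change-point sampler runs in seconds; the X is longer and denser in genes
    so that every X dose class is populated for curve fitting.
    """
    return [
        ArmSpec("2L", 500),
        ArmSpec("2R", 500),
        ArmSpec("3L", 500),
        ArmSpec("3R", 500),
        ArmSpec("X", 1000, is_x=True, n_genes=12000),
    ]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic data generator.

    Defaults are the study conditions: tetraploid autosomes / diploid X,
    ~42% / ~17% aneuploid coverage, copies 1-5, 2.29 RPKM per copy,
    EC50 = 2 saturating dose response, 1.35-fold MSL multiplier removed by
    RNAi, log-normal expression noise with CV 0.3, and an intergenic
    background calibrated so 5% of regions reach 4 RPKM.
    """

    arm_specs: list[ArmSpec] = field(default_factory=default_arm_specs)
    baseline_copy_autosome: int = 4
    baseline_copy_X: int = 2
    aneuploid_fraction_autosome: float = 0.42
    aneuploid_fraction_X: float = 0.17
    copy_range: tuple[int, int] = (1, 5)
    #: Aneuploid copies seen on the X (baseline 2; large amplifications of the
    #: male X are not observed, so the default stops at 3).
    x_copy_range: tuple[int, int] = (1, 3)
    #: RPKM of one genomic copy; None derives it from the genome so that the
    #: simulated arms receive exactly the whole read library (conservation).
    per_copy_rpkm_unit: float | None = DEFAULT_PER_COPY_RPKM
    #: Library size used as the RPKM denominator. The simulated arms receive
    #: their proportional share of these reads. The default puts ~460 reads
    #: in a tetraploid 1 kb window (density sd ~0.45 RPKM), deep enough that
    #: the +/- unit/2 copy bands are well separated at window level.
    total_dna_reads: int = 50_000_000
    n_genes_per_arm: int = 2500
    #: Natural-log location/spread of baseline expression (RPKM at baseline
    #: copy). Median exp(3.912) ~= 50 RPKM: the robustly expressed population
    #: that ratiometric analyses are restricted to.
    baseline_expression_log_mean: float = math.log(50.0)
    baseline_expression_log_sd: float = 1.0
    ec50: float = DEFAULT_EC50
    msl_multiplier: float = DEFAULT_MSL_MULTIPLIER
    #: Fraction of the MSL multiplier retained under RNAi (0 = complete
    #: knockdown; 0.1 emulates the >90% knockdown reported for the dsRNAs).
    knockdown_residual: float = 0.0
    expression_noise_cv: float = 0.3
    intergenic_count: int = 10_000
    #: RPKM ceiling of the intergenic background: the (1 - background_alpha)
    #: quantile of the background law equals this value.
    intergenic_scale: float = 4.0
    background_alpha: float = 0.05
    window_kb: int = 1
    min_segment_kb: int = 30
    max_segment_kb: int = 120
    gene_length_kb: tuple[int, int] = (1, 4)
    #: Fraction of genes deliberately placed across a segment boundary to
    #: exercise the spanning-gene exclusion rule.
    spanning_gene_fraction: float = 0.01
    #: Gamma-Poisson overdispersion of window counts (0 = pure Poisson).
    count_dispersion: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        for name in ("aneuploid_fraction_autosome", "aneuploid_fraction_X",
                     "background_alpha", "knockdown_residual",
                     "spanning_gene_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.per_copy_rpkm_unit is not None and self.per_copy_rpkm_unit <= 0:
            raise ValueError("per_copy_rpkm_unit must be > 0")
        if self.ec50 <= 0:
            raise ValueError("ec50 must be > 0")
        if self.msl_multiplier < 1:
            raise ValueError("msl_multiplier must be >= 1")
        lo, hi = self.copy_range
        if not (0 <= lo <= hi <= 6):
            raise ValueError("copy_range must be within [0, 6] and non-empty")
        xlo, xhi = self.x_copy_range
        if not (0 <= xlo <= xhi <= 6):
            raise ValueError("x_copy_range must be within [0, 6] and non-empty")
        if self.total_dna_reads <= 0:
            raise ValueError("total_dna_reads must be > 0")
        if self.intergenic_scale < 0:
            raise ValueError("intergenic_scale must be >= 0")
        if self.expression_noise_cv < 0:
            raise ValueError("expression_noise_cv must be >= 0")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be > 0")
        if not self.arm_specs:
            raise ValueError("at least one arm is required")
        for arm in self.arm_specs:
            if arm.length_kb < self.min_segment_kb:
                raise ValueError(
                    f"arm {arm.name} is shorter than one aneuploid segment")
            if arm.length_kb % self.window_kb:
                raise ValueError(
                    f"arm {arm.name} length must be a multiple of window_kb")

    # -- convenience --------------------------------------------------------

    def baseline_copy(self, is_x: bool) -> int:
        return self.baseline_copy_X if is_x else self.baseline_copy_autosome

    def genes_for(self, arm: ArmSpec) -> int:
        return arm.n_genes if arm.n_genes is not None else self.n_genes_per_arm

    def noise_log_sd(self) -> float:
        """Log-scale sigma of multiplicative noise with the configured CV."""
        return math.sqrt(math.log1p(self.expression_noise_cv ** 2))

    # -- (de)serialisation --------------------------------------------------

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["arm_specs"] = [asdict(a) for a in self.arm_specs]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["arm_specs"] = [ArmSpec(**a) for a in d["arm_specs"]]
        for key in ("copy_range", "x_copy_range", "gene_length_kb"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)
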