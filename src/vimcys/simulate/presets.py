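"""Versioned presets and assay constants for the synthetic-data generators.

Every default here encodes the study conditions the analyses assume: the
plate-reader kinetics design (triplicate wells, pH 3-10.8, sampling every
3 min up to 90 min), the wild-type two-ionization rate law (pKa 4.61 and
7.39), the Cys-to-Ser control (pH-independent background), the gel designs
encoding zinc's concentration-dependent and spacer-length-selective
protection, and the toy "nearby"/"distant" two-chain cysteine
arrangements.  Free parameters the source experiments do not pin down
(noise magnitudes, limiting rates, baseline band ratios) are fixed once
here and surfaced in generator metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "AssayConstants",
    "KineticsPreset",
    "GelCondition",
    "GelDesign",
    "IonSpec",
    "StructureArrangement",
    "WT_KINETICS",
    "C328S_KINETICS",
    "figure6a_design",
    "figure2d_design",
    "mg_dbb_design",
    "nacl_dbb_design",
    "nearby_arrangement",
    "distant_arrangement",
]


def _require_finite(name: str, *values: float) -> None:
    for v in values:
        if not math.isfinite(float(v)):
            raise ValueError(f"non-finite value in field {name!r}: {v}")


@dataclass(frozen=True)
class AssayConstants:
    """Fixed assay-scale constants (concentrations in uM unless noted)."""

    vimentin_extinction: float = 22450.0  # M^-1 cm^-1 at 280 nm
    kinetics_protein_conc: float = 2.5  # uM
    kinetics_probe_conc: float = 10.0  # uM MBB
    zincon_conc: float = 40.0  # uM
    competition_protein_conc: float = 5.0  # uM
    zincon_kd_nm: float = 214.0  # nM

    def __post_init__(self) -> None:
        for f, v in self.__dict__.items():
            _require_finite(f, v)
            if v <= 0:
                raise ValueError(f"{f} must be strictly positive")

    @property
    def probe_ratio(self) -> float:
        """mol/mol probe:protein ratio (10 uM MBB over 2.5 uM protein = 4)."""
        return self.kinetics_probe_conc / self.kinetics_protein_conc


#: Nominal pH grid of the kinetics plate (buffer series from pH 3 to 10.8).
DEFAULT_PH_GRID = (3.0, 3.5, 4.0, 4.5, 5.0, 5.5, 6.0, 6.5, 7.0, 7.5,
                   8.0, 8.5, 9.0, 9.5, 10.0, 10.8)
#: Sampling every 3 min up to 90 min.
DEFAULT_TIMES = tuple(float(t) for t in range(0, 91, 3))


@dataclass(frozen=True)
class KineticsPreset:
    """Generating parameters of one plate-reader kinetics experiment."""

    variant: str  # "wt" | "C328S"
    pka_values: tuple[float, ...]  # ascending, pH units
    limiting_rates: tuple[float, ...]  # min^-1, per ionization site
    baseline_rate: float  # min^-1, pH-independent
    f0: float = 50.0  # AU, initial (bottom-plateau) fluorescence
    fmax: float = 500.0  # AU, top plateau
    noise_sd: float = 4.0  # AU, additive Gaussian noise
    ph_grid: tuple[float, ...] = DEFAULT_PH_GRID
    times: tuple[float, ...] = DEFAULT_TIMES
    replicates: int = 3
    background_wells: int = 1  # no-protein wells per pH
    ph_jitter_sd: float = 0.03  # pH units, nominal -> measured offset
    curve_family: str = "logistic"  # "logistic" | "exponential"
    seed: int = 0

    def __post_init__(self) -> None:
        _require_finite("baseline_rate", self.baseline_rate)
        _require_finite("f0", self.f0)
        _require_finite("fmax", self.fmax)
        _require_finite("noise_sd", self.noise_sd)
        if self.pka_values:
            _require_finite("pka_values", *self.pka_values)
        if self.limiting_rates:
            _require_finite("limiting_rates", *self.limiting_rates)
        if list(self.pka_values) != sorted(self.pka_values):
            raise ValueError("pka_values must be sorted ascending")
        if len(self.pka_values) != len(self.limiting_rates):
            raise ValueError("limiting_rates must match pka_values in length")
        if not (self.fmax > self.f0 > 0):
            raise ValueError("need fmax > f0 > 0")
        if len(self.times) < 5 or not all(
                b > a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing with >=5 points")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.curve_family not in ("logistic", "exponential"):
            raise ValueError(f"unknown curve_family {self.curve_family!r}")


#: Wild type: two ionization sites at the experimentally determined pKa
#: values; limiting rates chosen so alkylation progresses over the 90-min
#: observation window.
WT_KINETICS = KineticsPreset(
    variant="wt",
    pka_values=(4.61, 7.39),
    limiting_rates=(0.025, 0.045),
    baseline_rate=0.002,
)

#: Cys328Ser control: no reactive thiol, small pH-independent background.
C328S_KINETICS = KineticsPreset(
    variant="C328S",
    pka_values=(),
    limiting_rates=(),
    baseline_rate=0.003,
)


@dataclass(frozen=True)
class GelCondition:
    """One design row of a gel experiment (control + treated lanes)."""

    variant: str
    agent: str
    agent_conc: float  # uM
    pre_salt: str  # none | ZnCl2 | MgCl2 | NaCl
    salt_conc: float  # uM
    true_inhibition: float  # fraction; negative = enhancement
    baseline_ratio: float  # expected band ratio without salt
    replicates: int = 3
    ratio_kind: str = "oligomer"  # oligomer | modification

    def __post_init__(self) -> None:
        if not (-1.0 <= self.true_inhibition <= 1.0):
            raise ValueError("true_inhibition must lie in [-1, 1]")
        if self.baseline_ratio <= 0:
            raise ValueError("baseline_ratio must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.ratio_kind not in ("oligomer", "modification"):
            raise ValueError(f"unknown ratio_kind {self.ratio_kind!r}")


@dataclass(frozen=True)
class GelDesign:
    rows: tuple[GelCondition, ...]
    noise_cv: float = 0.06  # coefficient of variation of band intensities
    reference_intensity: float = 1000.0  # AU, expected monomer/vimentin band
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def figure6a_design(noise_cv: float = 0.06, replicates: int = 3,
                    seed: int = 0) -> GelDesign:
    """Spacer-length selectivity of zinc protection at 500 uM ZnCl2.

    Encodes 76% inhibition of DBB crosslinking, 56% for TMEA, none for BMH
    (longest arm) and none for the amine-reactive control DST.
    """
    rows = []
    for agent, conc, inh, base, kind in (
        ("DBB", 24.0, 0.76, 1.0, "oligomer"),
        ("TMEA", 50.0, 0.56, 0.8, "oligomer"),
        ("BMH", 50.0, 0.0, 0.7, "oligomer"),
        ("DST", 50.0, 0.0, 2.0, "oligomer"),
    ):
        rows.append(GelCondition(variant="wt", agent=agent, agent_conc=conc,
                                 pre_salt="none", salt_conc=0.0,
                                 true_inhibition=0.0, baseline_ratio=base,
                                 replicates=replicates, ratio_kind=kind))
        rows.append(GelCondition(variant="wt", agent=agent, agent_conc=conc,
                                 pre_salt="ZnCl2", salt_conc=500.0,
                                 true_inhibition=inh, baseline_ratio=base,
                                 replicates=replicates, ratio_kind=kind))
    return GelDesign(rows=tuple(rows), noise_cv=noise_cv, seed=seed)


def figure2d_design(noise_cv: float = 0.06, replicates: int = 4,
                    seed: int = 0) -> GelDesign:
    """Concentration-dependent protection of Iac-B modification by ZnCl2."""
    doses = (0.0, 5.0, 10.0, 50.0, 100.0, 500.0)
    inhibition = (0.0, 0.20, 0.35, 0.60, 0.75, 0.85)  # monotone protection
    rows = tuple(
        GelCondition(variant="wt", agent="IacB", agent_conc=10.0,
                     pre_salt="ZnCl2" if d > 0 else "none", salt_conc=d,
                     true_inhibition=i, baseline_ratio=1.5,
                     replicates=replicates, ratio_kind="modification")
        for d, i in zip(doses, inhibition)
    )
    return GelDesign(rows=rows, noise_cv=noise_cv, seed=seed)


def mg_dbb_design(noise_cv: float = 0.06, replicates: int = 3,
                  seed: int = 0) -> GelDesign:
    """Magnesium control: no protection of alkylation, enhancement of the
    DBB-induced dimer band (negative inhibition)."""
    rows = (
        GelCondition("wt", "IacB", 10.0, "none", 0.0, 0.0, 1.5,
                     replicates, "modification"),
        GelCondition("wt", "IacB", 10.0, "MgCl2", 50.0, 0.0, 1.5,
                     replicates, "modification"),
        GelCondition("wt", "DBB", 24.0, "none", 0.0, 0.0, 1.0,
                     replicates, "oligomer"),
        GelCondition("wt", "DBB", 24.0, "MgCl2", 500.0, -0.30, 1.0,
                     replicates, "oligomer"),
    )
    return GelDesign(rows=rows, noise_cv=noise_cv, seed=seed)


def nacl_dbb_design(noise_cv: float = 0.06, replicates: int = 3,
                    seed: int = 0) -> GelDesign:
    """NaCl-induced polymerization enhances DBB crosslinking."""
    rows = (
        GelCondition("wt", "DBB", 24.0, "none", 0.0, 0.0, 1.0,
                     replicates, "oligomer"),
        GelCondition("wt", "DBB", 24.0, "NaCl", 150000.0, -0.50, 1.0,
                     replicates, "oligomer"),
    )
    return GelDesign(rows=rows, noise_cv=noise_cv, seed=seed)


@dataclass(frozen=True)
class IonSpec:
    """A placed ion: pinned near a cysteine SG or wandering far away."""

    element: str = "ZN"
    mode: str = "pinned"  # pinned | walk
    contact_distance: float = 2.5  # A; Zn-S coordination bond length
    walk_offset: float = 50.0  # A, distance of the walk's start from chain A SG
    walk_step_sd: float = 1.0  # A per frame

    def __post_init__(self) -> None:
        if self.mode not in ("pinned", "walk"):
            raise ValueError(f"unknown ion mode {self.mode!r}")
        if self.contact_distance <= 0:
            raise ValueError("contact_distance must be positive")


@dataclass(frozen=True)
class StructureArrangement:
    """Toy two-chain arrangement with a configurable Cys SG separation."""

    name: str = "custom"
    sg_distance: float = 4.0  # A
    n_frames: int = 1
    ions: tuple[IonSpec, ...] = ()
    frame_jitter_sd: float = 0.0  # A, per-coordinate Gaussian jitter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sg_distance <= 0:
            raise ValueError("sg_distance must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.frame_jitter_sd < 0:
            raise ValueError("frame_jitter_sd must be >= 0")


def nearby_arrangement(**kw) -> StructureArrangement:
    """The close arrangement: SG atoms of facing chains 4 A apart."""
    return StructureArrangement(name="nearby", sg_distance=4.0, **kw)


def distant_arrangement(**kw) -> StructureArrangement:
    """The far arrangement: SG atoms 22 A apart."""
    return StructureArrangement(name="distant", sg_distance=22.0, **kw)
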