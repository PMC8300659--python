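"""Quantification of modification and crosslinking from gel band tables.

Band intensities come from upstream densitometry (background-subtracted).
Two per-lane readouts are used: the biotin/vimentin ratio for probe
incorporation (modification), and the oligomer/monomer ratio for covalent
crosslinking.  Protection by a cation (Zn2+, Mg2+) is quantified as
percent inhibition of the mean ratio relative to a no-salt control group,
with Student's t-tests for group comparisons and a Spearman trend of
inhibition against crosslinker spacer-arm length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .registry import validate_registry, get as registry_get

__all__ = [
    "LaneRecord",
    "ProtectionResult",
    "modification_ratio",
    "oligomer_ratio",
    "lane_ratio",
    "percent_inhibition",
    "protection_vs_spacer",
    "compare_conditions",
    "lanes_to_frame",
    "frame_to_lanes",
]

GEL_COLUMNS = [
    "lane_id", "variant", "agent", "agent_conc_um", "pre_salt",
    "salt_conc_um", "replicate", "band", "intensity_au",
]


@dataclass
class LaneRecord:
    """Band intensities for one gel lane, with treatment metadata."""

    lane_id: str
    variant: str
    agent: str
    agent_conc: float  # uM
    pre_salt: str  # none | ZnCl2 | MgCl2 | NaCl
    salt_conc: float  # uM
    replicate: int
    bands: dict[str, float]  # band name -> intensity (AU)

    def __post_init__(self) -> None:
        for name, v in self.bands.items():
            if v < 0:
                raise ValueError(f"lane {self.lane_id!r}: negative {name} intensity")


@dataclass
class ProtectionResult:
    agent: str
    salt: str
    salt_conc: float  # uM
    ratio_control: float
    ratio_treated: float
    percent_inhibition: float  # %, negative means enhancement
    p_value: float
    test: str
    n: int
    ratio_kind: str = "oligomer"


def modification_ratio(lane: LaneRecord) -> float:
    """biotin/vimentin band ratio (probe incorporation per unit protein)."""
    if "biotin" not in lane.bands or "vimentin" not in lane.bands:
        raise ValueError(f"lane {lane.lane_id!r}: biotin and vimentin bands required")
    if lane.bands["vimentin"] <= 0:
        raise ValueError(f"lane {lane.lane_id!r}: vimentin band intensity is 0")
    return lane.bands["biotin"] / lane.bands["vimentin"]


def oligomer_ratio(lane: LaneRecord) -> float:
    """oligomer/monomer band ratio (extent of covalent crosslinking)."""
    if "oligomer" not in lane.bands or "monomer" not in lane.bands:
        raise ValueError(f"lane {lane.lane_id!r}: oligomer and monomer bands required")
    if lane.bands["monomer"] <= 0:
        raise ValueError(f"lane {lane.lane_id!r}: monomer band intensity is 0")
    return lane.bands["oligomer"] / lane.bands["monomer"]


_RATIOS = {"modification": modification_ratio, "oligomer": oligomer_ratio}


def lane_ratio(lane: LaneRecord, ratio_kind: str) -> float:
    try:
        return _RATIOS[ratio_kind](lane)
    except KeyError:
        raise ValueError(f"unknown ratio_kind {ratio_kind!r}") from None


def percent_inhibition(treated, control, ratio_kind: str = "oligomer",
                       paired: bool = False) -> ProtectionResult:
    """Percent inhibition of the band ratio in treated vs control lanes.

    Ratios are computed per lane, then averaged per group (never a ratio
    of group means); inhibition = (1 - mean_treated / mean_control) * 100,
    which may be negative when the treatment enhances the signal.
    """
    treated, control = list(treated), list(control)
    if not treated or not control:
        raise ValueError("both lane groups must be non-empty")
    agents = {ln.agent for ln in treated} | {ln.agent for ln in control}
    if len(agents) != 1:
        raise ValueError(f"lane groups mix agents: {sorted(agents)}")
    rt = np.array([lane_ratio(ln, ratio_kind) for ln in treated])
    rc = np.array([lane_ratio(ln, ratio_kind) for ln in control])
    if rc.mean() == 0:
        raise ValueError("control group mean ratio is 0; inhibition undefined")
    pi = (1.0 - rt.mean() / rc.mean()) * 100.0
    p, test = compare_conditions(rt, rc, paired=paired)
    salts = sorted({ln.pre_salt for ln in treated})
    concs = sorted({ln.salt_conc for ln in treated})
    return ProtectionResult(
        agent=agents.pop(), salt=salts[0] if len(salts) == 1 else "mixed",
        salt_conc=concs[0] if len(concs) == 1 else float("nan"),
        ratio_control=float(rc.mean()), ratio_treated=float(rt.mean()),
        percent_inhibition=float(pi), p_value=p, test=test,
        n=min(len(rt), len(rc)), ratio_kind=ratio_kind,
    )


def compare_conditions(group_a, group_b, paired: bool = False) -> tuple[float, str]:
    """Two-sided Student's t-test between two groups of per-lane values."""
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if paired:
        if len(a) != len(b) or len(a) < 2:
            raise ValueError("paired test needs >=2 matched pairs")
        if np.allclose(a, b):
            return 1.0, "paired t-test"
        res = stats.ttest_rel(a, b)
        return float(res.pvalue), "paired t-test"
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >=2 lanes per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return 1.0, "unpaired t-test"
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.pvalue), "unpaired t-test"


def protection_vs_spacer(results, registry=None) -> dict:
    """Spearman trend of percent inhibition vs crosslinker spacer-arm length.

    Returns pairs (spacer_arm, inhibition), the rank correlation rho, and a
    trend label: "inverse" (rho < 0), "direct" (rho > 0), or "flat" when
    all inhibitions tie (rho undefined).
    """
    results = list(results)
    if registry is None:
        from .registry import DEFAULT_REGISTRY
        registry = DEFAULT_REGISTRY
    registry = validate_registry(registry)
    agents = [r.agent for r in results]
    if len(set(agents)) != len(agents):
        raise ValueError("duplicate crosslinker entries in results")
    if len(results) < 3:
        raise ValueError("need results for >=3 crosslinkers")
    pairs = []
    for r in results:
        xl = registry_get(registry, r.agent)
        pairs.append((float(xl.spacer_arm), float(r.percent_inhibition)))
    pairs.sort()
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.ptp(y) == 0:
        return {"pairs": pairs, "rho": float("nan"), "p_value": float("nan"),
                "trend": "flat"}
    rho, p = stats.spearmanr(x, y)
    trend = "inverse" if rho < 0 else ("direct" if rho > 0 else "flat")
    return {"pairs": pairs, "rho": float(rho), "p_value": float(p), "trend": trend}


def lanes_to_frame(lanes) -> pd.DataFrame:
    """Long-format gel table (one row per band)."""
    rows = []
    for ln in lanes:
        for band in sorted(ln.bands):
            rows.append((ln.lane_id, ln.variant, ln.agent, ln.agent_conc,
                         ln.pre_salt, ln.salt_conc, ln.replicate, band,
                         ln.bands[band]))
    return pd.DataFrame(rows, columns=GEL_COLUMNS)


def frame_to_lanes(df: pd.DataFrame) -> list[LaneRecord]:
    lanes = []
    keys = ["lane_id", "variant", "agent", "agent_conc_um", "pre_salt",
            "salt_conc_um", "replicate"]
    for key, sub in df.groupby(keys, sort=False):
        lanes.append(LaneRecord(
            lane_id=key[0], variant=key[1], agent=key[2], agent_conc=float(key[3]),
            pre_salt=key[4], salt_conc=float(key[5]), replicate=int(key[6]),
            bands=dict(zip(sub["band"], sub["intensity_au"])),
        ))
    return lanes
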