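"""Synthetic gel/blot band-intensity tables.

Each design row yields `replicates` lanes.  The reference band (monomer
for crosslinking readouts, vimentin for modification readouts) has a fixed
expected intensity; the signal band (oligomer or biotin) has expected
intensity ``reference * baseline_ratio * (1 - true_inhibition)``.  Both
carry multiplicative lognormal noise at the design's coefficient of
variation, so expected ratios are preserved and intensities stay positive.
"""

from __future__ import annotations

import numpy as np

from ..densitometry import LaneRecord
from .presets import GelDesign

__all__ = ["make_gel_table"]

_BAND_NAMES = {"oligomer": ("oligomer", "monomer"),
               "modification": ("biotin", "vimentin")}


def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Draw with the requested mean and coefficient of variation."""
    if mean == 0.0:
        return 0.0
    if cv == 0.0:
        return mean
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def make_gel_table(design: GelDesign, seed: int | None = None) -> list[LaneRecord]:
    """Generate lanes for every design row; deterministic under a seed."""
    if design.noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(design.seed if seed is None else seed)
    lanes: list[LaneRecord] = []
    for row_i, row in enumerate(design.rows):
        signal_band, ref_band = _BAND_NAMES[row.ratio_kind]
        signal_mean = design.reference_intensity * row.baseline_ratio \
            * (1.0 - row.true_inhibition)
        for rep in range(1, row.replicates + 1):
            bands = {
                ref_band: _lognormal(rng, design.reference_intensity,
                                     design.noise_cv),
                signal_band: _lognormal(rng, signal_mean, design.noise_cv),
            }
            lanes.append(LaneRecord(
                lane_id=f"r{row_i}-{row.agent}-{row.pre_salt}{row.salt_conc:g}-{rep}",
                variant=row.variant, agent=row.agent, agent_conc=row.agent_conc,
                pre_salt=row.pre_salt, salt_conc=row.salt_conc, replicate=rep,
                bands=bands,
            ))
    return lanes
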