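"""Synthetic Zincon competition curves (A620 vs total zinc, +/- protein)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..competition import (BindingModel, CompetitionAssay, predict_absorbance,
                           solve_species)
from .presets import AssayConstants

__all__ = ["make_competition_curves", "DEFAULT_ZN_TOTALS"]

#: Default total-zinc titration grid, uM.
DEFAULT_ZN_TOTALS = tuple(float(z) for z in np.linspace(0.0, 60.0, 16))


def make_competition_curves(constants: AssayConstants, model: BindingModel,
                            zn_totals=DEFAULT_ZN_TOTALS, noise_sd: float = 0.0,
                            seed: int = 0) -> CompetitionAssay:
    """Paired with/without-protein A620 curves from the equilibrium solver.

    The protein-free curve uses protein_total = 0; the protein curve uses
    ``constants.competition_protein_conc``.  Gaussian noise of ``noise_sd``
    (AU) is added to both.
    """
    zn_totals = np.asarray(list(zn_totals), dtype=float)
    if np.any(zn_totals < 0):
        raise ValueError("zn_totals must be non-negative")
    rng = np.random.default_rng(seed)
    assay = CompetitionAssay(
        zincon_total=constants.zincon_conc,
        protein_total=constants.competition_protein_conc,
        points=pd.DataFrame(columns=["zn_total_um", "a620", "with_protein"]),
    )
    rows = []
    for with_protein in (False, True):
        pt = constants.competition_protein_conc if with_protein else 0.0
        for zt in zn_totals:
            state = solve_species(float(zt), assay, model, protein_total=pt)
            a = predict_absorbance(state, model)
            if noise_sd > 0:
                a += rng.normal(0.0, noise_sd)
            rows.append((float(zt), float(a), with_protein))
    assay.points = pd.DataFrame(rows, columns=["zn_total_um", "a620",
                                               "with_protein"])
    return assay
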