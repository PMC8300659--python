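"""Determine the cysteine pKa from pH-dependent alkylation kinetics.

Reads the simulated plates (or regenerates three independent wild-type
experiments), converts each well to k_obs, fits the k_obs-vs-pH titration
with 0/1/2-ionization models, and pools the pKa estimates.  Finding: the
wild type is biphasic with pKa near 4.6 and 7.4; the Cys-to-Ser control
selects the pH-independent baseline model.

Writes results/kobs_wt.csv, results/pka_fits.json, results/pka_pooled.csv.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from vimcys.alkylation import build_titration_curve, frame_to_traces
from vimcys.simulate import C328S_KINETICS, WT_KINETICS, make_kinetics_plate
from vimcys.titration import fit_pka, pool_experiments, select_model


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    # experiment 1 comes from the saved CSV (exercising the I/O schema);
    # two more independent experiments are generated on the fly
    wt_csv = args.data / "kinetics_wt.csv"
    if wt_csv.exists():
        plates = [frame_to_traces(pd.read_csv(wt_csv))]
    else:
        plates = [make_kinetics_plate(WT_KINETICS, seed=args.seed)]
    plates += [make_kinetics_plate(WT_KINETICS, seed=args.seed + i)
               for i in (1, 2)]

    fits, report = [], {"experiments": []}
    for i, plate in enumerate(plates, 1):
        curve = build_titration_curve(plate)
        if i == 1:
            pd.DataFrame({
                "ph_final": curve.ph, "kobs_min^-1": curve.kobs,
                "sem": curve.sem, "n": [p.n for p in curve.points],
            }).to_csv(args.out / "kobs_wt.csv", index=False)
        fit = fit_pka(curve, n_sites=2)
        fits.append(fit)
        report["experiments"].append({
            "experiment": i, "pka": fit.pka, "limiting_rates_min^-1":
            fit.limiting_rates, "baseline_min^-1": fit.baseline,
            "r_squared": fit.r_squared, "aicc": fit.aicc,
        })
        print(f"experiment {i}: pKa = {fit.pka[0]:.2f} / {fit.pka[1]:.2f} "
              f"(R^2 = {fit.r_squared:.3f})")

    pooled = pool_experiments(fits)
    print(f"pooled (n={pooled.n_experiments}): "
          f"pKa1 = {pooled.mean[0]:.2f} +/- {pooled.sd[0]:.2f}, "
          f"pKa2 = {pooled.mean[1]:.2f} +/- {pooled.sd[1]:.2f} (mean +/- SD)")

    mut_curve = build_titration_curve(
        make_kinetics_plate(C328S_KINETICS, seed=args.seed))
    mut_model = select_model(mut_curve)
    print(f"Cys-to-Ser control: model selection keeps {mut_model.n_sites} "
          f"ionization site(s); R^2 = {mut_model.r_squared:.3f}")

    report["pooled"] = {"mean": pooled.mean, "sd": pooled.sd,
                        "n_experiments": pooled.n_experiments}
    report["control_selected_sites"] = mut_model.n_sites
    (args.out / "pka_fits.json").write_text(json.dumps(report, indent=1))
    pd.DataFrame({"site": [1, 2], "pka_mean": pooled.mean,
                  "pka_sd": pooled.sd}).to_csv(
        args.out / "pka_pooled.csv", index=False)


if __name__ == "__main__":
    main()
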