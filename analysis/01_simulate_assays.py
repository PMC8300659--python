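"""Generate every synthetic dataset the downstream analyses consume.

Writes, under results/data/:
  kinetics_wt.csv / kinetics_c328s.csv  - plate-reader MBB kinetics
  gel_spacer.csv                        - spacer-selectivity gel design
  gel_zinc_dose.csv                     - Iac-B modification vs ZnCl2 dose
  competition.csv                       - Zincon A620 titrations +/- protein
  nearby.pdb / distant.pdb              - two-chain Cys arrangements
  traj_nearby.pdb                       - 10-frame jittered trajectory with
                                          2 pinned + 3 wandering Zn ions
  metadata.json                         - generator settings incl. noise
"""

import argparse
import dataclasses
import json
from pathlib import Path

from vimcys.alkylation import traces_to_frame
from vimcys.competition import BindingModel, assay_to_frame
from vimcys.densitometry import lanes_to_frame
from vimcys.simulate import (AssayConstants, C328S_KINETICS, IonSpec,
                             WT_KINETICS, distant_arrangement,
                             figure2d_design, figure6a_design,
                             make_competition_curves, make_gel_table,
                             make_kinetics_plate, make_structure_fixture,
                             nearby_arrangement)

TRUE_BINDING = BindingModel(kd_protein_um=0.5, n_sites=2.0)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    traces_to_frame(make_kinetics_plate(WT_KINETICS, seed=args.seed)) \
        .to_csv(out / "kinetics_wt.csv", index=False)
    traces_to_frame(make_kinetics_plate(C328S_KINETICS, seed=args.seed)) \
        .to_csv(out / "kinetics_c328s.csv", index=False)

    lanes_to_frame(make_gel_table(figure6a_design(seed=args.seed))) \
        .to_csv(out / "gel_spacer.csv", index=False)
    lanes_to_frame(make_gel_table(figure2d_design(seed=args.seed))) \
        .to_csv(out / "gel_zinc_dose.csv", index=False)

    assay = make_competition_curves(AssayConstants(), TRUE_BINDING,
                                    noise_sd=0.0158, seed=args.seed)
    assay_to_frame(assay).to_csv(out / "competition.csv", index=False)

    make_structure_fixture(nearby_arrangement(), path=out / "nearby.pdb")
    make_structure_fixture(distant_arrangement(), path=out / "distant.pdb")
    make_structure_fixture(
        nearby_arrangement(
            n_frames=10, frame_jitter_sd=0.2,
            ions=(IonSpec(mode="pinned"), IonSpec(mode="pinned"),
                  IonSpec(mode="walk"), IonSpec(mode="walk"),
                  IonSpec(mode="walk")),
            seed=args.seed),
        path=out / "traj_nearby.pdb")

    meta = {
        "seed": args.seed,
        "wt_kinetics": dataclasses.asdict(WT_KINETICS),
        "c328s_kinetics": dataclasses.asdict(C328S_KINETICS),
        "gel_noise_cv": figure6a_design().noise_cv,
        "competition_truth": {"kd_protein_um": TRUE_BINDING.kd_protein_um,
                              "n_sites": TRUE_BINDING.n_sites,
                              "noise_sd_au": 0.0158},
    }
    (out / "metadata.json").write_text(json.dumps(meta, indent=1))
    print(f"wrote synthetic datasets to {out}/ (seed {args.seed})")


if __name__ == "__main__":
    main()
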