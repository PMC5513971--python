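#!/usr/bin/env python
"""Calibrate the ring likelihood from the single-landmark condition.

Collapses the 1-landmark endpoints onto the distance-to-landmark axis,
fits the radial Gaussian, and writes the ridge parameters for both model
variants.  These two numbers (ridge radius and central spread) are the
only fitted parameters in the whole analysis; everything downstream is a
parameter-free prediction.
"""

import argparse
from pathlib import Path

from landmark_homing import exp1_configuration
from landmark_homing.fitting import (
    EndpointSet,
    fit_single_landmark_condition,
    save_params,
)
from landmark_homing.synthetic import generate_experiment1


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--endpoints", type=Path, default=None,
                    help="endpoint CSV (default: regenerate experiment 1)")
    ap.add_argument("--out-dir", type=Path, default=Path("results/fits"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    if args.endpoints is not None:
        endpoints = EndpointSet.load(args.endpoints)
    else:
        endpoints, _ = generate_experiment1(seed=args.seed)
    calib = endpoints.subset(condition_id="lm1")
    landmark = exp1_configuration("visual", 1).test_landmarks[0]

    for variant in ("gaussian", "mixture"):
        params = fit_single_landmark_condition(calib, landmark, variant=variant)
        save_params(params, args.out_dir / f"params_{variant}.json")
        msg = (
            f"{variant:8s}: ridge_radius = {params.ridge_radius:.3f} vm, "
            f"sigma_center = {params.sigma_center:.3f} vm"
        )
        if variant == "mixture":
            msg += (
                f" (pedestal: sigma_tail = {params.sigma_tail:.1f} vm, "
                f"amplitude = {params.tail_amplitude:.2f}, fixed by rule)"
            )
        print(msg)
    print(f"wrote fitted parameters to {args.out_dir}/")


if __name__ == "__main__":
    main()
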