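"""Demonstrate the peak-displacement confound mechanism.

Constructs a material pair (half the stiffness, higher viscosity) whose
double-push peak displacement matches the background within 1%, then images a
lesion made of that material: the PD map cannot see it while the RE map
separates the two regions by a factor of 2.  This is the mechanism by which
viscosity degrades displacement-derived stiffness reading.
"""

import argparse
from pathlib import Path

import numpy as np

from visrsim import (AcousticsSpec, MaterialPoint, TrackingSequenceSpec,
                     compute_images, confound_pair, double_push_schedule,
                     make_phantom, peak_displacement, tracking_times,
                     voigt_response)
from visrsim.phantom import PhantomSpec


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results/confound"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    seq = TrackingSequenceSpec()
    _, times = tracking_times(seq)
    sched = double_push_schedule(seq)
    e1, mu1 = 3.0, 0.6
    e2, mu2 = confound_pair(e1, mu1, seq)
    pd1 = peak_displacement(voigt_response(MaterialPoint(e1, mu1), sched,
                                           times))
    pd2 = peak_displacement(voigt_response(MaterialPoint(e2, mu2), sched,
                                           times))
    print(f"background: E = {e1} kPa, mu = {mu1} Pa*s  -> PD {pd1:.3f} um")
    print(f"confound:   E = {e2} kPa, mu = {mu2:.3f} Pa*s -> PD {pd2:.3f} um")
    print(f"PD ratio {pd2 / pd1:.4f}; stiffness differs by {e1 / e2:.1f}x, "
          f"viscosity by {mu2 / mu1:.1f}x")

    spec = PhantomSpec(grid_shape=(256, 40), axial_spacing=0.15625,
                       lesion_E=e2, lesion_mu=mu2, background_E=e1,
                       background_mu=mu1, lesion_axes=(6.0, 4.0))
    ph = make_phantom(spec)
    img = compute_images(ph, seq, AcousticsSpec(attenuation_db_cm_mhz=0.0))
    img.save_png(args.out / "confound_images.png")
    m = ph.bmode_mask
    print(f"image medians, lesion vs background: "
          f"PD {np.median(img.pd[m]) / np.median(img.pd[~m]):.3f} "
          f"(invisible), RE {np.median(img.re[m]) / np.median(img.re[~m]):.3f} "
          f"(0.5x, fully separated), "
          f"RV {np.median(img.rv[m]) / np.median(img.rv[~m]):.3f}")
    print(f"renderings -> {args.out}")


if __name__ == "__main__":
    main()
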