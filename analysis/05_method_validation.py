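"""Stage 5 — system-suitability and validation statistics at the optimized method.

Simulates replicate injections at the optimized conditions and computes
the validation panel: retention times, USP tailing, theoretical plates,
resolution, %RSD of areas and retention, recovery across three QC
levels, S/N and the S/N = 3 detection limit.  Writes the panel to
results/validation/.
"""

import json
from pathlib import Path

import numpy as np

from chromdoe import chromsim, quantval

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "validation"
OPTIMIZED = {"flow": 0.6, "volume": 18.0, "organic_init": 82.0,
             "wavelength": 270.0, "organic_late": 95.0}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    windows = chromsim.peak_windows(OPTIMIZED)

    areas, tailings, retentions = {0: [], 1: []}, {0: [], 1: []}, {0: [], 1: []}
    for rep in range(6):
        chrom = chromsim.simulate_chromatogram(OPTIMIZED, seed=SEED * 1000 + rep)
        for i, w in enumerate(windows):
            ts, ys = chrom.window(*w)
            areas[i].append(chromsim.peak_area(chrom, w))
            tailings[i].append(chromsim.usp_tailing(chrom, w))
            retentions[i].append(float(ts[np.argmax(ys)]))

    chrom = chromsim.simulate_chromatogram(OPTIMIZED, seed=SEED)
    rs = chromsim.resolution(chrom, windows[0], windows[1])
    plates = [chromsim.theoretical_plates(chrom, w) for w in windows]
    sn = [chromsim.sn_ratio(chrom, w, (0.2, 1.8)) for w in windows]

    # LOD from the linear height response and the baseline noise level.
    heights = []
    for conc in (2.0, 5.0, 10.0):
        t = chromsim.DrugTemplate(
            **{**chromsim.STP_TEMPLATE.__dict__, "concentration": conc}
        )
        c = chromsim.simulate_chromatogram(
            OPTIMIZED, templates=(t,), noise_sd=0.0, injection_cv=0.0
        )
        _, ys = c.window(*chromsim.peak_windows(OPTIMIZED, templates=(t,))[0])
        heights.append(ys.max())
    slope = quantval.calibration_fit([2.0, 5.0, 10.0], heights).slope
    lod = chromsim.lod_from_calibration(slope, chromsim.DEFAULT_NOISE_SD)

    # Recovery at three QC levels through an area calibration.
    def stp_area(conc, seed=0):
        t = chromsim.DrugTemplate(
            **{**chromsim.STP_TEMPLATE.__dict__, "concentration": conc}
        )
        c = chromsim.simulate_chromatogram(OPTIMIZED, templates=(t,), seed=seed)
        return chromsim.peak_area(c, chromsim.peak_windows(OPTIMIZED, templates=(t,))[0])

    cal_conc = np.array([0.78, 3.12, 6.25, 12.5, 25.0])
    curve = quantval.calibration_fit(cal_conc, [stp_area(c) for c in cal_conc])
    recoveries = {}
    for qc in (0.78, 6.25, 25.0):
        measured = float(curve.inverse(stp_area(qc, seed=SEED + 7)))
        recoveries[qc] = chromsim.recovery(measured, qc)

    panel = {
        "retention_min": {d: float(np.mean(retentions[i]))
                          for i, d in enumerate(("STP", "HI443"))},
        "usp_tailing": {d: float(np.mean(tailings[i]))
                        for i, d in enumerate(("STP", "HI443"))},
        "theoretical_plates": {d: plates[i] for i, d in enumerate(("STP", "HI443"))},
        "resolution": rs,
        "sn_ratio": {d: sn[i] for i, d in enumerate(("STP", "HI443"))},
        "area_rsd_pct": {d: chromsim.rsd(areas[i])
                         for i, d in enumerate(("STP", "HI443"))},
        "retention_rsd_pct": {d: chromsim.rsd(retentions[i])
                              for i, d in enumerate(("STP", "HI443"))},
        "calibration_r2": curve.r2,
        "lod_ug_ml": lod,
        "recovery_pct": {str(k): v for k, v in recoveries.items()},
    }
    (OUT / "validation_panel.json").write_text(json.dumps(panel, indent=2))

    print("System suitability at the optimized conditions (n = 6):")
    print(f"  retention: STP {panel['retention_min']['STP']:.2f} min, "
          f"HI443 {panel['retention_min']['HI443']:.2f} min")
    print(f"  USP tailing: STP {panel['usp_tailing']['STP']:.2f}, "
          f"HI443 {panel['usp_tailing']['HI443']:.2f}  (criterion < 2)")
    print(f"  plates: STP {panel['theoretical_plates']['STP']:.0f}, "
          f"HI443 {panel['theoretical_plates']['HI443']:.0f}  (criterion > 3000)")
    print(f"  resolution Rs = {rs:.1f}  (criterion > 2)")
    print(f"  area %RSD: STP {panel['area_rsd_pct']['STP']:.2f}%, "
          f"HI443 {panel['area_rsd_pct']['HI443']:.2f}%  (criterion < 2%)")
    print(f"  calibration r2 = {curve.r2:.5f}  (criterion > 0.99)")
    print(f"  LOD (S/N = 3): {lod:.3f} ug/mL")
    rec = ", ".join(f"{k}: {v:.1f}%" for k, v in panel["recovery_pct"].items())
    print(f"  recovery at QC levels (ug/mL): {rec}  (criterion 90-110%)")
    print(f"Panel written to {OUT}")


if __name__ == "__main__":
    main()
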