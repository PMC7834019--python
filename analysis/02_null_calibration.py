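"""Calibrate the navigation indices on salt-blind worms.

Simulates cohorts of 200 worms with both strategy gains set to zero on
the default 19-h gradient and runs the full analysis pipeline (track
smoothing off, pirouette detection, dC/dt and dC/dn sampling, index
computation).  A correctly calibrated pipeline must report chemotaxis,
pirouette and weathervane indices centred on zero: any systematic
offset would masquerade as a salt preference of a salt-blind animal.

Writes results/null_calibration.json.
"""

import argparse
import json
from pathlib import Path

import saltnav as sn

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seeds", type=int, default=10)
    ap.add_argument("--n-worms", type=int, default=200)
    args = ap.parse_args()

    geom = sn.PlateGeometry()
    field = sn.build_field(geom)
    null = sn.SimWormParams(klinokinesis_gain=0.0, klinotaxis_gain=0.0)

    ci, pir, wv = [], [], []
    for seed in range(args.seeds):
        res = sn.simulate_worms(sn.SimConfig(geometry=geom, field=field,
                                             n_worms=args.n_worms,
                                             duration=900.0, seed=seed), null)
        counts = sn.count_endpoint_areas(res.final_positions(), geom)
        ci.append(sn.chemotaxis_index(counts))
        nav = sn.plate_navigation_indices(res.tracks, field)
        pir.append(nav.pirouette_index)
        wv.append(nav.weathervane_index)

    out = {}
    for name, values in (("chemotaxis_index", ci),
                         ("pirouette_index", pir),
                         ("weathervane_index", wv)):
        mean, sem = sn.per_plate_aggregate(values)
        out[name] = {"mean": mean, "sem": sem, "per_seed": values,
                     "centred_on_zero": bool(abs(mean) < 2 * sem)}
        print(f"{name:22s} {mean:+.4f} +/- {sem:.4f} "
              f"({'ok' if abs(mean) < 2 * sem else 'BIASED'})")

    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "null_calibration.json").write_text(json.dumps(out, indent=1))


if __name__ == "__main__":
    main()
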