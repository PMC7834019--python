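"""Recover the navigation-strategy gains from simulated behaviour.

Two experiments on the default gradient (50 worms, 540 s, 10 seeds
each):

* klinotaxis -- sweep the steering gain over {0, 1, 2}
  (deg/mm)/(mM/mm) and check that the weathervane regression slope
  tracks it;
* klinokinesis -- flip the sign of the pirouette-rate gain and check
  that the pirouette index follows, and that positive gains also drive
  the endpoint chemotaxis index positive (migration toward high salt).

Writes results/strategy_recovery.json.
"""

import argparse
import json
from pathlib import Path

import numpy as np

import saltnav as sn

RESULTS = Path(__file__).resolve().parents[1] / "results"


def _cohort(field, geom, params, seed):
    res = sn.simulate_worms(sn.SimConfig(geometry=geom, field=field,
                                         n_worms=50, duration=540.0,
                                         seed=seed), params)
    return res, sn.plate_navigation_indices(res.tracks, field)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seeds", type=int, default=10)
    args = ap.parse_args()

    geom = sn.PlateGeometry()
    field = sn.build_field(geom)
    out = {"klinotaxis": {}, "klinokinesis": {}}

    for g_wv in (0.0, 1.0, 2.0):
        params = sn.SimWormParams(klinotaxis_gain=g_wv)
        slopes = [_cohort(field, geom, params, s)[1].weathervane_index
                  for s in range(args.seeds)]
        mean, sem = sn.per_plate_aggregate(slopes)
        out["klinotaxis"][str(g_wv)] = {"mean_slope": mean, "sem": sem}
        print(f"g_wv = {g_wv:.0f}: recovered slope {mean:+.3f} +/- {sem:.3f}")

    for g_kk in (0.1, -0.1):
        params = sn.SimWormParams(klinokinesis_gain=g_kk, klinotaxis_gain=0.0)
        idx, ci = [], []
        for s in range(args.seeds):
            res, nav = _cohort(field, geom, params, s)
            idx.append(nav.pirouette_index)
            ci.append(sn.chemotaxis_index(
                sn.count_endpoint_areas(res.final_positions(), geom)))
        sign_hits = int(np.sum(np.sign(idx) == np.sign(g_kk)))
        mean, sem = sn.per_plate_aggregate(idx)
        out["klinokinesis"][str(g_kk)] = {
            "mean_index": mean, "sem": sem,
            "sign_consistent_seeds": sign_hits,
            "mean_chemotaxis_index": float(np.mean(ci))}
        print(f"g_kk = {g_kk:+.1f}: pirouette index {mean:+.4f} +/- {sem:.4f} "
              f"(sign consistent {sign_hits}/{args.seeds} seeds), "
              f"endpoint CI {np.mean(ci):+.3f}")

    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "strategy_recovery.json").write_text(json.dumps(out, indent=1))


if __name__ == "__main__":
    main()
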