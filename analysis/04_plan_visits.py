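#!/usr/bin/env python
"""Plan clinic visits for obtaining SHL and EHL PK profiles.

Compares three logistics: the combined schedule (SHL trough drawn at the EHL
dosing visit, SHL dose given at the EHL trough visit), fully separate
profiles without predose reuse, and an EHL-only profile.

Writes: results/visit_plans.json
"""

import argparse
import json
from pathlib import Path

from pklss import plan_schedule


def show(title, plan):
    print(f"\n{title}: {plan.n_samples} samples, {plan.n_visits} visits")
    for e in plan.events:
        where = f"visit {e.visit}" if e.visit is not None else "at home"
        print(f"  {e.time_h:+8.2f} h  {where:9s} {e.concentrate:4s} {e.action:12s} {e.label}")
    return {
        "n_samples": plan.n_samples,
        "n_visits": plan.n_visits,
        "events": [
            {"visit": e.visit, "time_h": e.time_h, "action": e.action,
             "concentrate": e.concentrate, "label": e.label}
            for e in plan.events
        ],
    }


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    plans = {
        "combined": show("combined SHL + EHL profiling",
                         plan_schedule("LSS7", "SHL_no4h", mode="combined", predose_reuse=True)),
        "separate": show("separate profiles, no predose reuse",
                         plan_schedule("LSS7", "SHL_no4h", mode="separate", predose_reuse=False)),
        "ehl_only": show("EHL-only profile",
                         plan_schedule("LSS7", None, predose_reuse=True)),
    }
    with open(args.out / "visit_plans.json", "w") as fh:
        json.dump(plans, fh, indent=2)
    print(f"\nwrote {args.out}/visit_plans.json")


if __name__ == "__main__":
    main()
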