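"""Label ovitrap slat records with the 28-day establishment rule.

Builds a handful of one-trap seasons by hand, applies the run rule, and
shows how analyzed/unanalyzed slats and the strict comparator change the
decision.
"""

import pandas as pd

from aedesrisk import assign_period, trap_establishment


def season(positives, analyzed=None, start="2010-05-21", step_days=14):
    n = len(positives)
    analyzed = [True] * n if analyzed is None else analyzed
    dates = pd.date_range(start, periods=n, freq=f"{step_days}D")
    return pd.DataFrame(
        {
            "trap_id": "T1",
            "year": 2010,
            "collection_date": dates,
            "analyzed": analyzed,
            "positive": [bool(p) and a for p, a in zip(positives, analyzed)],
        }
    )


cases = {
    "three consecutive positives (days 0/14/28)": season([1, 1, 1]),
    "two positives only (span 14 d)": season([1, 1]),
    "alternating +/-/+/-/+": season([1, 0, 1, 0, 1]),
    "alternate rounds, 28 d apart, two positives": season([1, 1], step_days=28),
    "positive / unanalyzed / positive": season([1, 0, 1], analyzed=[True, False, True]),
}

print("Establishment rule: a run of consecutive positive analyzed slats")
print("spanning >= 28 days marks the trap-year as established.\n")
for name, slats in cases.items():
    established, runs = trap_establishment(slats)
    spans = [r.span_days for r in runs]
    print(f"{name:46s} -> established={established}  run spans (days): {spans}")

print("\nStrict comparator (> 28 days) on the alternate-round case:")
est_strict, _ = trap_establishment(season([1, 1], step_days=28), strict=True)
print(f"  established={est_strict}  (two alternate-round positives span exactly 28 d)")

print("\nBiweekly surveillance periods for a few dates:")
for d in ("2010-05-20", "2010-07-15", "2010-09-30", "2010-12-01"):
    print(f"  {d} -> period {assign_period(d)}")
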