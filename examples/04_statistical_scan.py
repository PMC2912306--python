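"""Locate a differential peak with the chromatographic statistical scan.

Simulates two sets of three replicate runs that are identical except for one
analyte spiked 5-fold in the first set, then scans the TICs for retention-
time regions that are both statistically different (Welch, p < 0.05) and
beyond a 2-fold intensity ratio.  Exactly one region, containing the spiked
analyte's retention time, should be reported.
"""

from gcmspipe import make_panel, simulate_run, statistical_scan
from gcmspipe.simgen import NoiseParams

panel = make_panel(n_analytes=4, rt_range=(300.0, 370.0), seed=4)
spiked = next(a for a in panel.analytes
              if panel.submix[a.name] is not None)
noise = NoiseParams(baseline=30, cv=0.05, additive_sd=5)

base = {a.name: 1.0 for a in panel.analytes}
high = dict(base, **{spiked.name: 5.0})

runs_a = [simulate_run(panel, high, noise, seed=10 + k, run_id=f"a{k}")[0]
          for k in range(3)]
runs_b = [simulate_run(panel, base, noise, seed=20 + k, run_id=f"b{k}")[0]
          for k in range(3)]

regions = statistical_scan(runs_a, runs_b, alpha=0.05, min_ratio=2.0)
print(f"spiked analyte: {spiked.name} at rt {spiked.rt_true:.1f} s")
print(f"{len(regions)} significant region(s):")
for r in regions:
    print(f"  rt {r.rt_lo:.2f}-{r.rt_hi:.2f} s   min p = {r.min_p:.2e}   "
          f"mean ratio = {r.mean_ratio:.2f}")
print("The region brackets the spiked retention time; unspiked peaks are")
print("suppressed by the fold-change gate even when noise makes them")
print("nominally significant.")
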