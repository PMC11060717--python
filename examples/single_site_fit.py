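"""Global single-site Kd fit with bootstrap uncertainty.

Simulates a titration of ~100 uM protein with a ligand binding one common
site (true Kd 154 uM), fits all combined-CSP curves globally with one
shared Kd and per-residue amplitudes, and attaches a bootstrap confidence
interval.  The printed Kd should land within a few percent of the truth.
"""

from shiftbind import (
    estimate_uncertainty,
    fit_single_site,
    make_truth,
    simulate_titration,
)

truth = make_truth("single_site", seed=7)  # sigma = 0.005 ppm by default
ds = simulate_titration(truth)

fit = fit_single_site(ds, ds.residues)
fit = estimate_uncertainty(fit, ds, ds.residues, method="bootstrap", n_boot=200, seed=7)

kd = fit.global_params["Kd"]
lo, hi = fit.ci["Kd"]
print(f"true Kd        : {truth.Kd:.1f} uM")
print(f"fitted Kd      : {kd:.1f} uM  (95% CI {lo:.1f} - {hi:.1f})")
print(f"curves / points: {fit.n_curves} / {fit.n_points}, rss = {fit.rss:.3g} ppm^2")
print(f"starts agreeing: {fit.n_starts_agreeing}/7 multi-start optima within 1%")
print("The shared Kd is the dissociation constant; each curve's amplitude is")
print("that residue's shift change at full saturation.")
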