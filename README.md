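# shiftbind

Quantitative analysis of NMR-detected protein–ligand titrations and
exchange spectroscopy, built around the binding chemistry of the prolyl
isomerase Pin1 engaging the phosphorylated C-terminal tail of protein
kinase C: chemical-shift-perturbation (CSP) profiling, global
dissociation-constant fitting for single-site and two-independent-site
equilibria with an exact free-ligand solution, EXSY cis–trans
exchange-kinetics fitting, and the thermodynamic bookkeeping of bivalent
(avidity) binding. A synthetic-data generator with recorded ground truth
makes every stage testable without spectrometer data.

Intended users: NMR spectroscopists and structural biologists fitting
HSQC titration series or EXSY buildup curves, and anyone who needs a
tested reference implementation of these standard analyses.

## The models

**Combined CSP.** For each residue, the amide cross-peak displacement
between apo and ligand-bound states is collapsed to
Δ = √(Δδ_H² + (0.152·Δδ_N)²) (ppm). Residues feeding the binding curves
must have Δ strictly above the profile mean, be in fast exchange, and be
resolved.

**Single-site isotherm (with ligand depletion).** For P + L ⇌ PL at total
concentrations P₀, L₀,

Δ = Δ_max · [P₀+L₀+K_d − √((P₀+L₀+K_d)² − 4P₀L₀)] / (2P₀)

**Two independent sites.** When the WW and PPIase domains bind the same
ligand independently with constants K_d,W and K_d,I, each residue's curve
follows Δ = A·[L]/(K_d+[L]) with its domain's constant, and the free
ligand [L] is the physical root of the cubic mass balance, evaluated by
the trigonometric (Viète) solution plus a Newton polish. Fits share
(K_d,W, K_d,I) globally across all ¹H and ¹⁵N curves with one amplitude
per curve.

**EXSY kinetics.** Two-state cis–trans exchange gives the
cross-peak/diagonal buildup
I_ct/I_tt = k_tc·[1 − e^(−k_EX·t_mix)] / (k_ct + k_tc·e^(−k_EX·t_mix)),
k_EX = k_tc + k_ct, with plateau k_tc/k_ct equal to the cis:trans
population ratio. The experiment detects 0.1 ≤ k_EX ≤ 100 s⁻¹.

**Bivalency thermodynamics.** fold = K_d,ref/K_d and
ΔΔG° = −RT·ln(fold) with R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹, T = 298.15 K by
default; component ΔΔG° values add, folds multiply.

## Worked example

`python examples/two_site_fit.py` simulates a titration of a 100 μM
bidomain protein against a phosphopeptide binding the WW site at 257 μM
and the PPIase site at 75 μM (0.005 ppm peak-position noise), selects
responsive residues by the CSP rule, and refits both constants globally:

```
true  Kd_W = 257 uM, Kd_I = 75 uM
fitted Kd_W = 271.0 uM, Kd_I = 71.8 uM
20 curves (1H and 15N per residue), 180 observations
site preference: PPIase site bound 3.8x more tightly than WW
```

The fitted pair lands within a few percent of truth; the ratio of the two
constants is the domain preference of the ligand.
`python examples/bivalency_ledger.py` then shows the thermodynamic
ledger: the two phosphate groups contribute 62-fold and 14-fold affinity
gains (−2.4 and −1.6 kcal/mol), combining to 868-fold ≈ −4.0 kcal/mol.
The other examples cover CSP selection, single-site fitting with
bootstrap confidence intervals, and EXSY rate fitting.

A thin CLI wraps the same library calls:

```sh
shiftbind simulate --scenario single_site --seed 1 --out-dir run/
shiftbind fit --input run/titration.csv --config run/config.json --out-dir run/
shiftbind thermo --records kd.csv --comparisons cmp.json --out-dir run/
```

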