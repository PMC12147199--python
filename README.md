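# gqstack

**Stacking equilibrium of telomeric G-quadruplex multimers: coarse-grained
Monte Carlo, SAXS forward modelling, and an exact transfer-matrix
helix–coil model.**

The single-stranded 3′ overhang of human telomeres carries enough TTAGGG
repeats to fold into several consecutive G-quadruplex (GQ) units joined by
short TTA linkers. Whether those units stack into a rigid column or dangle
as beads on a string controls ligand binding sites, telomerase access and
the mechanics of the chromosome end. `gqstack` is a library (plus CLI) for
quantifying that stacking–unstacking equilibrium, aimed at biophysicists
who combine solution scattering with coarse-grained simulation.

It has three layers:

1. **ECG Monte Carlo** (`gqstack.geometry`, `gqstack.mc`): each GQ is an
   impenetrable hard cylinder (R = 1.48 nm, H = 2.21 nm); consecutive units
   are joined by an infinite-square-well tether on the rims of the facing
   bases (range L_max, the TTA linker) and attract through a finite square
   well of depth u0 on the facing base centers (range δ, stacking).
   Metropolis sampling at the dimensionless temperature T\* = k_BT/u0 gives
   equilibrium ensembles; T\* = ∞ turns the attraction off.
2. **SAXS forward model and fitter** (`gqstack.saxs`): orientation-averaged
   coherent scattering of cylinder configurations,
   I(q) = ⟨|Σᵢ Vᵢ Aᵢ(q,αᵢ) e^{i q·rᵢ}|²⟩ with the classic cylinder
   amplitude A = [2J₁(qR sin α)/(qR sin α)]·sinc(qH cos α/2); χ² grid
   search over (R, H, T\*) with scale and background profiled out.
3. **Transfer-matrix helix–coil model** (`gqstack.helix_coil`): each unit
   is stacked (B) or unstacked (U) with conditional weights
   q(B|·) = s, q(U|B) = 1, q(U|U) = σ; the 2×2 transfer matrix
   G = [[σ, 1], [s, s]] yields the closed-form partition function Q_n(s, σ)
   for any chain length, the stacked fraction f_n = s/(n−1) ∂ ln Q_n/∂s,
   stacking free energies ΔG_s(n) = −k_BT(n−1) ln(f_n/(1−f_n)), and
   unstacked-multiplet statistics — the analytic bridge from short
   simulated chains to arbitrarily long telomeric overhangs.

`gqstack.synthetic` generates every pipeline input (noisy SAXS curves,
stacked-fraction series, planted angle mixtures) from known ground truth,
so the entire workflow is testable offline; `gqstack.analysis` turns
ensembles into observables (bonded fractions with block-averaged errors,
junction-angle mixtures, chance-bonding rates, U-turn bending fractions).
See `docs/methods.md` for the model details, calibration and limitations.

## Worked example

Fit the transfer-matrix weights to stacked fractions measured on 2–4-unit
chains and extrapolate to longer multimers:

```bash
$ cat fn.csv
n,fn,err
2,0.315,0.001
3,0.350,0.001
4,0.369,0.001

$ gqstack pipeline --fn-csv fn.csv --n-max 8 --out-dir out
fitted s=0.4581+-0.0021 sigma=0.7618+-0.0056
wrote out/predictions.csv and out/report.json

$ head -5 out/predictions.csv
n,fn,dG_stack_kcal_mol,dG_per_junction
2,0.314159749031984,0.45458736867242167,0.45458736867242167
3,0.3538022695995196,0.7014562908138934,0.3507281454069467
4,0.3660142798795904,0.9595835835251421,0.3198611945083807
5,0.3721432345750174,1.2181435804475569,0.3045358951118892
```

Reading the output: s < 1 says a stacked junction costs free energy
(ΔG_s(2) = −k_BT ln s ≈ +0.45 kcal/mol at 293 K), so most junctions are
open at equilibrium — the multimer is mostly beads-on-a-string. σ < 1 is
the excluded-volume penalty on two consecutive open junctions; it makes
f_n creep upward with chain length (0.314 → 0.380 by n = 8) while the
destabilization per junction, ΔG_s/(n−1), falls from 0.45 to
0.28 kcal/mol. The same numbers predict how many m-unit unstacked pockets
a long overhang offers to junction-binding ligands
(`gqstack predict --s 0.4581 --sigma 0.7618 --n-max 10`).

Simulation-side, the same quantities come from the Monte Carlo layer
without the analytic model:

```bash
gqstack simulate --n-units 2 --sweeps 200000 --seed 3 --out-dir sim2
gqstack analyze sim2/trajectory.npz --out-dir sim2
```

and a scattering curve is fitted with
`gqstack saxs-fit curve.dat --q-units nm --seed 1`.

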