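# fuzzbind

Analysis toolkit for **fuzzy complexes between disordered proteins and RNA**,
built around the model system of a small, highly cationic intrinsically
disordered protein (SERF, 68 residues, net charge +12) binding a folded
29-nucleotide RNA stem-loop (the HIV-1 TAR apical fragment) and, at high
concentrations, undergoing charge-driven complex coacervation.

Quantifying such an interaction requires a pipeline rather than a single
measurement, and this package implements each stage as tested library code:

* **Sequence charge analytics** — net charge (Arg/Lys +1, Asp/Glu −1, His 0;
  −1 per ribonucleotide), windowed net charge per residue (NCPR), and the
  charge-matched protein:RNA mixing ratio |z_RNA|/z_protein.
* **Binding isotherms** — fluorescence-anisotropy models with exact ligand
  depletion: the 1:1 mass-balance quadratic
  [PR] = ((P+R+K_D) − √((P+R+K_D)² − 4PR))/2 and a sequential 2:1 model,
  weighted nonlinear fitting of K_D,app with 95% confidence intervals, and
  AICc model comparison.
* **Coarse-grained simulation** — one protein + one RNA at one bead per
  residue/nucleotide in a periodic box, Wang–Frenkel short-range +
  Debye–Hückel screened electrostatics, BAOAB Langevin dynamics with rigid
  bodies for folded RNA conformers. Bound fraction f_b gives the in-box
  apparent constant K_D = (1 − f_b)²/(f_b·V·N_A); contact maps and
  bound/unbound Rg statistics are extracted per frame.
* **Ensemble observables** — per-frame Rg with KDE distributions, mean
  inter-residue distance maps normalized by an analytical Flory-random-coil
  null model (⟨r_ij⟩ ∝ |i−j|^0.5), PRE intensity-ratio profiles from
  Γ₂ = K·τ_c·⟨r⁻⁶⟩, reduced-representation Debye scattering with Guinier
  (I ≈ I₀e^{−q²Rg²/3}) and dimensionless Kratky analysis, dihedral-based
  helicity, Cα/Cβ secondary-structure propensities, and chemical-shift
  perturbations.
* **Phase analysis** — turbidity titration features (peak/plateau/onset),
  salt-dependence verdicts, and two-phase diagrams from concentration grids.
* **Synthetic data** — seeded generators for every input (titrations, chain
  ensembles, toy RNA hairpin conformers, turbidity curves) with truth
  records, so every stage is testable without downloads.

The bundled SERF sequence is a synthetic stand-in that matches the published
composition constraints (68 residues, net +12, nine Arg, one proline,
ERDK-rich); see its FASTA header.

## Worked example

```python
from fuzzbind import net_charge, charge_matched_ratio
from fuzzbind.io import read_fasta
from fuzzbind.binding import fit_isotherm
from fuzzbind.observables import afrc_reference
from fuzzbind.synthetic import gen_titration
import importlib.resources as ir

data = ir.files("fuzzbind.data")
serf = read_fasta(str(data / "serf_synthetic.fasta"), kind="protein")[0]
tar = read_fasta(str(data / "tar.fasta"), kind="rna")[0]

print(net_charge(serf), net_charge(tar))        # 12 -29
print(round(charge_matched_ratio(serf, tar), 3))  # 2.417

series, truth = gen_titration(kd=0.67e-6, noise_sd=0.002, seed=1)
fit = fit_isotherm(series)
print(round(fit.kd_app[0] * 1e6, 3))            # 0.698  (uM, truth 0.67)

print(round(afrc_reference(68).rg, 1))          # 20.8   (A)
```

The charge bookkeeping says ~2.4 protein molecules neutralize one RNA, which
is where coacervation turbidity is expected to peak; the isotherm fit
recovers the generating micromolar constant within its confidence interval;
and the random-coil null predicts a 20.8 Å Rg against which measured
ensembles are judged expanded or compact.

A CLI mirrors the workflow (`fuzzbind synth | simulate | fit-binding |
observables | phase | report`), e.g.

```sh
fuzzbind synth --what titration --seed 3 --out out/synth
fuzzbind fit-binding --input out/synth/titration.csv --model both --out out/fit
```

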