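# Methods

This note records the models, conventions and numerical choices behind
`rotamerbh`, and what the synthetic systems do and do not establish.

## Angles and the torsional metric

All angles are degrees in the half-open interval (−180, 180], with the
IUPAC sign convention for dihedrals (mirror images negate the angle).
The distance between two side-chain conformations **p**, **q** with the
same number n of χ dihedrals is the Euclidean norm of the per-χ
shortest-arc differences. It is implemented *unnormalized* (no 1/n
factor): a cutoff c on this aggregate distance then implies every per-χ
difference is below c, i.e. the aggregate criterion is strictly stricter
than the same cutoff applied per dihedral — the property that justifies
using one cutoff (40°) for both clustering and per-χ matching.

Canonical χ definitions (χ1–χ4 heavy-atom quadruples per residue type) are
shipped as a plain-text table, with the three histidine protonation states
(HID/HIE/HIP) sharing one χ topology and generic HIS queries falling back
to the δ-protonated entry. ALA and GLY carry no χ; PRO is excluded as
conformationally locked by its ring. Two-fold symmetric terminal dihedrals
(PHE/TYR χ2, ASP χ2, GLU χ3) are kept as computed by default; folding into
(−90, 90] is available behind a flag (`fold_symmetric`) since force-field
and experimental conventions differ here.

## Clustering

Average-linkage (UPGMA) agglomeration runs directly on the periodic
distance table — angles are never re-embedded. The implementation is
in-package rather than delegated so two conventions are explicit and
deterministic:

* **tie-break** — among equal-distance merge candidates, the pair with the
  lexicographically smallest cluster ids merges first;
* **cut semantics** — two leaves share a flat cluster iff they merge at a
  height *strictly below* the cutoff (a merge at exactly 40° stays split).

The tests check the implementation against two independent routes: a naive
oracle that recomputes all inter-cluster average distances from the leaf
distance matrix at every merge, and scipy's average-linkage on the same
condensed tables.

## Rotamer statistics

Within a cluster, the per-χ mean is the circular mean (direction of the
resultant vector); the spread is the root-mean-square shortest-arc
deviation from that mean — a population (not sample) statistic that equals
the ordinary standard deviation for tight clusters while remaining correct
across the ±180° wrap. Singleton clusters are assigned a 1.0° spread to
stand in for the variance of displacements about their minimum. Occupation
probabilities are Boltzmann equilibrium populations of the member
conformations' free energies at the library temperature (298 K,
k_B = 1.987204259·10⁻³ kcal mol⁻¹ K⁻¹), summed over the cluster.
Probabilities are *not* renormalized after pruning (threshold 0.005,
strictly-below removed); consumers such as the rotamer move renormalize
over a context's surviving entries at draw time. Matching uses the per-χ
criterion (every χ strictly within 40° of the rotamer mean); the
reference-rotamer tracker defaults to the same per-χ criterion with the
aggregate-metric variant behind a flag, since either reading is defensible.

## Basin-hopping

Local minimization is scipy's L-BFGS-B with analytic gradients, run to a
maximum-gradient-component (hence RMS) force tolerance of
10⁻⁶ kcal mol⁻¹ Å⁻¹; non-convergence flags the record instead of raising.
Acceptance compares each candidate to the current Markov-chain minimum;
ties (Δ = 0) accept. When a step triggers both backbone and side-chain
moves, the backbone group rotation is applied first so imposed rotamer χ
values survive into minimization. Group rotations draw the rotation angle
uniformly in [−amplitude, +amplitude] with a 180° default — the magnitude
distribution is otherwise unconstrained — and move only the atoms
downstream of the rotated bond, preserving bond lengths and angles
exactly. Scheme-driven moves select *exactly* n_BB backbone dihedrals
(and, for group-rotation schemes, n_SC χ dihedrals pooled over all
residues) without replacement; the independent per-dihedral selection mode
(probability 0.025) used for library-construction-style runs is kept as a
separate option. One seeded generator drives every stochastic choice, so
trajectories are bit-reproducible given (inputs, seed, scheme).

Harmonic local free energies use unit masses: F = V + k_B T Σⱼ ln ωⱼ over
normal modes with Hessian eigenvalue above a 10⁻⁸ floor (zero modes from
overall translation/rotation are skipped; an eigenvalue below −10⁻⁸ raises,
as the point is not a minimum). Hessians come from the potential when
analytic, else central finite differences of the gradient (step 10⁻⁴).
F is defined up to an additive constant shared by all minima of one
system, which cancels in acceptance and in population ratios. The
thermodynamic temperature entering F is 298 K by default; the Metropolis
sampling temperature is a separate parameter in energy units
(1.3 kcal/mol in all benchmark presets).

## Synthetic systems: what they emulate, what they don't

**Planted ensembles.** `sample_planted_ensemble` draws conformations
around planted χ centers with wrapped Gaussian noise truncated at ±4σ
(σ = 5° by default — comparable to observed intra-rotamer spreads and well
inside the 40° cut; a von Mises draw would add nothing at σ ≪ 360°).
Draw counts per center are multinomial over the centers' Boltzmann weights
at 298 K. Each draw's free energy is the center free energy plus
k_B T ln n_c plus a ±0.05 kcal/mol uniform jitter: the ln n_c term makes
the *summed* population of a center's draws equal the center's planted
Boltzmann weight (a basin's total weight is split across its member
minima), so library recovery is insensitive to multinomial fluctuations in
the counts; the jitter keeps minima within a basin non-degenerate. In the
recovery checks the planted free-energy spreads are kept ≤ ~0.9 kcal/mol so
every center retains enough draws (≳ 20 of 200) for its circular mean to be
determined to ~1°. These ensembles emulate the *statistical* shape of
minimized tripeptide ensembles — tight basins, Boltzmann-weighted
occupancy — not their energetics: passing recovery tests shows the
clustering/probability pipeline is correct, not that any force field's
rotamer populations are.

**Rotamer chain.** The enumerable benchmark system is a bead chain:
backbone beads with two-bead side chains, harmonic bonds (r₀ = 1.5 Å,
k = 30 kcal mol⁻¹ Å⁻²) and angles (θ₀ = 109.47°, k = 15 kcal mol⁻¹ rad⁻²),
double-well backbone dihedrals (trans favored, second well +1.5 kcal/mol),
per-residue multi-well χ terms (von-Mises-shaped wells, concentration
κ = 8 ≈ 20° width, seeded depths in [1, 3] kcal/mol, centers evenly spaced
±10° jitter), and a soft r⁻¹²-like repulsion (ε = 1, σ = 2.2 Å, softened
core) between beads ≥ 4 bonds apart. The force constants are chosen soft
enough to keep L-BFGS well-conditioned yet stiff relative to the
1.3 kcal/mol sampling scale. The repulsion couples neighbouring side
chains, so the global minimum is not always the product of per-residue
deepest wells — the frustration that makes probability-informed rotamer
moves genuinely informative. Every combination of side-chain wells ×
backbone wells is built and minimized at construction (capped at 10⁵
combinations), de-duplicated on rounded torsions; the deepest catalogued
minimum is the exact global minimum, making "success within 1 kcal/mol"
decidable without external references. An energy/gradient kernel compiled
with numba serves the hot path; a pure-numpy implementation of the same
terms remains as fallback and as a cross-check in the tests.

**Scheme benchmark scale.** The shipped comparison (4 residues × 3 wells,
2000-step budget, 20 seeds, scheme `rotamer 2` vs `group rotation 2` —
the matched-cadence pair) is desk-scale: its 3⁴·2³ = 648 well combinations
are small enough that *both* move families reach the global minimum within
the budget, so the success-rate comparison saturates at the ceiling and
the discriminating observable is the number of steps to first success,
where rotamer moves are consistently ~2–3× faster (medians reported by the
acceptance script). Absolute success-rate gaps like those seen on real
peptides with a molecular-mechanics force field require systems whose side
chain packing is combinatorially hard, which is outside what an enumerable
toy can provide.

## File formats

Libraries serialize to a TSV with a `#key=value` header (temperature,
cutoff, prune, provenance) and one rotamer per row (context, up to four χ
means and spreads, probability, member count), rows ordered by context and
descending probability, floats written in shortest round-trip form — the
write→read→write cycle is byte-identical. Ensembles travel as multi-model
PDB plus a TSV energy sidecar (energies are kept out of PDB REMARKs for
robustness across dialects), or as a flat conformation TSV. Models missing
required side-chain atoms are flagged and excluded rather than fatal;
malformed ATOM records report their line number.

## Known limitations

* No force field: library quality on real peptides depends entirely on the
  supplied ensemble energies; the package validates machinery, not
  energetics.
* Backbone ϕ/ψ binning, ω/cis-proline handling and mmCIF input are out of
  scope; the library is backbone-independent by construction.
* The harmonic free energy assumes unit masses and classical harmonic
  wells; only free-energy *differences* between minima of one system are
  meaningful.
* Ring systems cannot be rotated (a dihedral inside a ring raises), which
  is also why proline is excluded.
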