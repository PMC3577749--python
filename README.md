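# pepdimer

Conformational-ensemble and binding-energetics analysis for peptide
heterodimers, built around the system of an amyloidogenic eleven-residue
peptide — apoC-II(60–70), sequence `MSTYTGIFTDQ` — bound to its
disulfide-cyclised derivative cyc(60–70) (the same sequence flanked by
cysteines).  The cyclic peptide is a "Janus" fibril inhibitor: one
hydrophobic face (Met60, Tyr63, Ile66, Phe67) and one hydrophilic face.
The package is aimed at structural bioinformaticians who have
multi-model PDB ensembles of such two-peptide systems (plus
umbrella-sampling window data and per-structure total energies) and want
the full analysis chain as reusable, tested Python.

## What it computes

- **RMSD clustering** — all-pairs backbone RMSD (Kabsch superposition),
  single-linkage clustering realized as connected components of the graph
  with an edge wherever d(i,j) < cutoff, medoid representatives, and the
  cutoff-selection rule: the smallest candidate yielding <10 clusters
  and/or a largest cluster holding ≤30 % of frames (2 Å backbone is the
  shipped default).
- **Hydrogen-bond persistence** — geometric detection (donor–acceptor
  ≤ 3.5 Å, H–donor–acceptor ≤ 30°), bond × frame existence profiles,
  per-key persistence fractions and per-frame means, with bonds keyed as
  e.g. `Gln70(NH)→Met60(O)` or `Ser61(OG,HG)→Asp69(OD1)`.
- **Secondary structure** — a DSSP-style classifier from backbone H-bond
  energies, E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol
  with a −0.5 kcal/mol threshold, producing H/G/I/E/B/T/C timelines.
- **Shape landscape** — end-to-end distance D_N–C vs radius of gyration
  R_g (reported in nm), gridded density, basin detection, and placement of
  cluster representatives.
- **Ring orientation** — the angle between the Cα→Cγ vectors of Tyr63 and
  Phe67, histogrammed over 41 bin centers spanning 0–180° (4.5° apart);
  angles < 90° mean both rings sit on one face (the fibril-inhibiting
  arrangement).
- **Umbrella sampling / WHAM** — harmonic-bias windows w_i(ξ) = ½k(ξ−ξ_i)²
  combined by the self-consistent pair
  P(b) = Σᵢnᵢ(b) / Σᵢ Nᵢ e^(−β(wᵢ(b)−fᵢ)),
  e^(−βfᵢ) = Σ_b P(b) e^(−βwᵢ(b)),
  PMF = −k_BT ln P shifted to zero at its minimum, plateau-based
  dissociation ΔG, and the aromatic minimum-contact vs COM-separation
  profile.
- **Interaction enthalpies** — E_i = E(complex) − E(A) − E(B) from supplied
  total energies, per-cluster mean ± sd (n−1), relative enthalpies against
  the most stable cluster, and the association summary table.
- **Synthetic ground truth** (`pepdimer.synthetic`) — Metropolis samplers
  on analytic 1D potentials for the WHAM machinery, and ideal-geometry
  peptide templates (extended / helix / hairpin / cyclic) with planted
  cluster memberships, H-bond geometries, ring angles and end-to-end
  distances, so every statistic can be validated against known answers.

## Worked example

```bash
python examples/cluster_ensemble.py
```

```
selected cutoff: 2.0 A
clusters found:  4
  cluster 1:  35.0 %   representative frame 61
  cluster 2:  28.5 %   representative frame 123
  cluster 3:  21.5 %   representative frame 147
  cluster 4:  15.0 %   representative frame 67
planted populations: [35.  28.5 21.5 15. ]
```

A 200-frame synthetic heterodimer ensemble mixing four templates (two
extended-like and two hairpin-like linear conformers bound at different
positions of the cyclic peptide) is clustered at the 2 Å backbone cutoff;
the recovered populations equal the planted mixture exactly, and each
cluster's medoid frame is reported.  Similarly:

```bash
python examples/wham_pmf.py
```

```
windows: 26, converged in 2010 iterations
double-well recovery RMS: 0.044 kcal/mol
dissociation free energy: 2.91 kcal/mol (planted 3.0)
plateau: 10.2-12.5 A, minimum at 1.98 A
```

Twenty-six umbrella windows 0.5 Å apart (k = 20 kcal/mol/Å², 300 K)
over U(x) = 2(x²−1)² reproduce the analytic double well to 0.04 kcal/mol
RMS, and a planted 3 kcal/mol binding well yields its dissociation free
energy from the PMF plateau.  The other examples cover H-bond persistence
(`hbond_persistence.py`), ring orientations and landscape basins
(`ring_landscape.py`) and the enthalpy table (`enthalpy_table.py`).

A thin CLI wraps the same library calls:

```bash
pepdimer synth --n-frames 200 --seed 0 --out fixtures/
pepdimer analyze --traj fixtures/trajectory.pdb --out report/
pepdimer wham --windows fixtures/windows/windows.csv --out pmf/
pepdimer energetics --energies energies.csv --out tables/
```

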