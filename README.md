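# kemlead

Lead-structure prediction with the counterpoise-corrected kernel energy
method (KEM-CP).

Docking scoring functions pick binding poses cheaply but unreliably: their
accuracy depends on the active-site environment and the resolution of the
target structure. A fragment-based quantum-crystallographic alternative
scores each docked pose by its protein–ligand interaction energy instead.
`kemlead` implements that pipeline for computational chemists and
structure-based drug-design practitioners: it fragments a protein–ligand
complex into hydrogen-capped kernels, assembles interaction energies from
single- and double-kernel energies with counterpoise averaging, clusters
docked poses into orientation types, adjudicates each scoring method's
best pose against the crystallographic ligand geometry, and compares
ligand rankings with experimental IC50 values.

## The method

A macromolecular system is partitioned into *kernels* — one active-site
residue or the ligand each, severed bonds capped with hydrogens. From
single-kernel energies $E_i$ and double-kernel energies $E_{ij}$ the total
energy is reconstructed as

$$E_\mathrm{total} = \sum_{i<j} E_{ij} \;-\; (n-2)\sum_{i=1}^{n} E_i ,$$

and the pairwise interaction energy of two kernels is

$$I_{ij} = E_{ij} - E_i - E_j .$$

With the ligand as the first kernel and each active-site residue as the
second, the protein–ligand interaction energy is the sum of the
ligand–residue $I_{ij}$. Each $I_{ij}$ is computed twice — raw and
counterpoise-corrected (Boys–Bernardi, removing basis-set superposition
error) — and the two are averaged; the averaged IE is the headline score
(more negative = stronger predicted binding).

A selected pose type counts as *correct* when its heavy-atom in-place RMSD
to the crystallized ligand is ≤ 2.0 Å. Docking fitness scores are ingested
as data, never computed.

Two energy backends satisfy one contract: a built-in classical
Coulomb + Lennard-Jones backend (exactly pairwise-additive, which makes the
kernel reconstruction analytically exact — the testing oracle for the whole
assembly layer), and an external-QM interface that writes two-fragment
counterpoise job files in the Gaussian input dialect and parses
counterpoise summary lines from logs.

## Worked example

Published per-ligand results for three targets — human aldose reductase
(hAR), cyclin-dependent kinase 2 (CDK2) and estrogen receptor β (ERβ) —
ship as packaged CSV fixtures. Adjudicating them:

```python
import kemlead as K

for target in ("hAR", "CDK2", "ERbeta"):
    t = K.summarize_target(K.load_fixture_records(target))
    print(target, f"GoldScore {t.fitness_correct}/{t.n_ligands} ({t.fitness_pct}%)",
          f"KEM-CP {t.ie_correct}/{t.n_ligands} ({t.ie_pct}%)")
```

prints

```
hAR GoldScore 3/5 (60%) KEM-CP 5/5 (100%)
CDK2 GoldScore 7/7 (100%) KEM-CP 6/7 (86%)
ERbeta GoldScore 7/10 (70%) KEM-CP 9/10 (90%)
```

i.e. the docking score alone picks the correct pose for 60–100% of ligands
depending on how hydrophobic the pocket is, while the interaction-energy
criterion stays at 86–100% across all three environments. Comparing
ligand rankings with experimental potency (rank 1 = most potent):

```python
recs = K.load_fixture_records("CDK2")
ic50 = K.rank_ligands(recs, key="ic50")
ie = K.rank_ligands(recs, key="avg_ie")
print(K.rank_agreement(ie, ic50))
```

```
RankAgreement(percent=64.28571428571428, method='spearman')
```

so the IE-based ranking of the seven CDK2 ligands agrees with the IC50
ranking at Spearman 64.3% (71.4% when restricted to the Type-1 poses).

The same stages are available as a shell pipeline (`kemlead prep`,
`fragment`, `energy`, `ie`, `poses`, `adjudicate`, `rank`, `simulate`);
`kemlead simulate` emits a fully parameterized synthetic complex so the
entire pipeline can be exercised without any external data.

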