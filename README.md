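# ampaflex

Quantitative analysis of conformational heterogeneity in AMPA-receptor
(AMPAR) structural ensembles, with matching electrophysiology kinetics
tools and fully ground-truthed synthetic data generators.

AMPARs are tetrameric glutamate-gated cation channels built from three
stacked layers: the N-terminal domain (NTD) tier, the ligand-binding domain
(LBD) tier and the transmembrane channel. In GluA2-lacking receptors such
as the GluA1 homomer the NTD dimers lose their tetrameric interface and
become highly mobile — they splay, tilt and even allow the NTD/LBD domain
swap to be undone — and the LBD subunits of the B/D positions rotate by up
to ~90° in desensitized states. `ampaflex` implements the measurements used
to put numbers on this behaviour:

- **Tilt/splay angles** (`domain_geometry`). For each NTD dimer, the angle
  between its local two-fold axis (second principal axis of its Cα
  positional covariance, d̂) and the global two-fold axis of a reference
  receptor (first principal axis, r̂):

  θ = arccos(d̂ · r̂), with θ → 180° − θ when the raw eigenvector points
  down towards the LBD (axes are sign-canonicalized deterministically).
  One (a, b) angle pair per model spans the conformational landscape.

- **Ensemble PCA and morphs** (`ensemble_modes`). PCA of the 3N-dimensional
  Cα coordinate vectors *without* prior superposition (covariance
  normalized by the number of frames M), eigenvector cosine overlaps
  between mode sets, and closed 20-frame morph trajectories along each
  principal component, scaled either to a target RMSD (e.g. 20.0 Å) or by a
  variance-weighted scale factor c·√λ.

- **LBD rotation angles** (`rotation_analysis`). Rotation of each LBD about
  a vertical axis through the chain's anchor residue (K501/K505 at the
  S1–M1 linker), measured as the vertex angle between a model's helix-G
  centre of mass, a pooled reference point and the reference structure's
  helix-G centre of mass.

- **Classification consensus** (`class_consensus`). Fractions of particles
  in a category of interest (domain-swapped vs non-swapped) across repeated
  cryo-EM classifications, with run consistency assessed by maximum-weight
  one-to-one class matching of co-migrating particle subsets, summarized as
  mean ± s.e. over the consistent runs (k in [6, 20] by default).

- **Kinetics** (`kinetics`). Bi-exponential desensitization decay fits with
  the weighted time constant
  τ_w = τ_f·A_f/(A_f+A_s) + τ_s·A_s/(A_f+A_s);
  two-pulse recovery fits ratio(t) = 1 − (1 − r₀)·e^(−t/τ_rec);
  paired-pulse train normalization; rectification index
  RI = −(I₊₄₀ − I₀)/(I₋₆₀ − I₀).

- **Synthetic data** (`synthetic_data`). A two-fold symmetric four-chain
  scaffold with planted dimer splays, LBD rotations and coordinate noise;
  replicated particle classifications with a planted swapped fraction and
  label noise; current sweeps with planted decay/recovery constants. Every
  generator records its ground truth, so every analysis above can be
  validated end to end.

## Worked example

Generate a 12-model synthetic ensemble with random planted splay angles
(uniform in [0°, 60°], 0.2 Å coordinate noise) and measure it:

```sh
$ ampaflex simulate ensemble --n 12 --seed 7 --out demo
wrote reference + 12 models to demo
$ ampaflex tilt --models demo/models --reference demo/reference.pdb \
    --selections demo/selections.yaml --out demo/angles.csv
wrote 12 rows to demo/angles.csv
$ head -4 demo/angles.csv
model_id,angle_a_deg,angle_b_deg,corrected_a,corrected_b
model_000,37.59705396,53.84556094,False,True
model_001,4.01498887,35.67190430,False,True
model_002,6.31142917,37.33503617,False,True
```

`angle_a_deg`/`angle_b_deg` are the two dimers' tilt angles in degrees
(0 = upright, 90 = splayed horizontal); `corrected_*` flags models where
the raw eigenvector pointed down and the 180° complement rule fired. The
planted values for `model_000` were (37.51°, 53.83°) — recovery is within
~0.1° at this noise level. The same directory feeds `ampaflex pca`,
`ampaflex morph --mode 1 --rmsd 20.0` (a 20-frame closed morph whose
extreme frames sit exactly 20.0 Å RMSD from the mean) and
`ampaflex rotation`.

Closed-form quantities print directly:

```sh
$ ampaflex kinetics ri --i-minus60 -600 --i-0 0 --i-plus40 160
0.2667
```

and `weighted_tau(5.0, 0.8, 50.0, 0.2)` returns `14.0` ms.

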