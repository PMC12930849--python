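# pkatraj

Track and analyze the pKa of ionizable residues along molecular-dynamics
trajectories.

The protonation propensity of an ionizable residue (Asp, Glu, His, Cys, Tyr,
Lys, Arg, and the chain termini) depends on its local environment, which
changes with protein conformation. Single-structure pKa predictors such as
PROPKA estimate, for one structure, the shift of each residue's pKa from its
model value (the pKa of the isolated amino acid in solution). `pkatraj` turns
such a per-structure predictor into a trajectory analysis: it iterates the
engine over every sampled frame of an MD ensemble and analyzes the resulting
per-residue pKa time series. It is aimed at people post-processing
conventional (fixed-protonation) MD who want to know which residues have
conformation-dependent pKa values — e.g. to flag residues whose protonation
state assignment deserves a second look, or to link pKa excursions to
specific contacts and collective motions.

## What it computes

For an ensemble with frames *t* = 1..*T* and ionizable residues *i*, the
engine yields a matrix pKa_i(t) (and, for PROPKA, a buried ratio in %).
On top of that matrix the package provides:

- **Summaries and distributions** — per-residue mean, sd, min/max, the shift
  Δ = ⟨pKa_i⟩ − pKa_model(i), binned histograms, and running-average time
  evolutions (centered window, e.g. 5 ns).
- **Protonation-sensitivity flags** — the fraction of frames with
  pKa_i(t) ∈ [pH − w, pH + w] (default pH 7.4, w = 1), the range where both
  protonation states have significant populations.
- **Pseudo-mutation** — re-predict after replacing selected residues with
  alanine *in place* (side chain truncated at CB, every other coordinate
  untouched), to attribute a residue's pKa shift to specific neighbours.
  This probes the wild-type structure; it is not a mutant pKa estimate.
- **Correlation scanning** — Pearson (or Spearman) correlation of every
  pKa_i(t) against user-supplied time-dependent properties, typically
  principal-component projections of the trajectory (the projections are an
  input; the package does not compute trajectory PCA).
- **Environment clustering** — frames described by pKa values, buried ratios
  and minimum heavy-atom inter-residue distances of selected residues;
  features Z-scored, optionally PCA-reduced, clustered with k-medoids,
  greedy (leader), DBSCAN or HDBSCAN; hyperparameters optimized by grid
  search on the mean silhouette width; one representative structure written
  per cluster.
- **Structure mapping** — per-residue values (frame pKa, trajectory mean, or
  Δ from model) written into the B-factor column of an annotated PDB with a
  companion PyMOL-style `.pml` color-spectrum script.

Engines are pluggable: `propka` (default; needs the `propka` package),
`pkai` (needs `pKAI`), and a deterministic geometric `mock` engine used for
testing and plumbing validation. The external engines are called through
their published APIs and are never re-implemented. Prediction parallelizes
by splitting frames into contiguous per-worker ranges; merged output is
identical for any worker count.

## Worked example

No external data is needed — the package generates a synthetic peptide
ensemble (extended chain, sinusoidal coherent motion) whose geometry the
deterministic mock engine converts into pKa series:

```sh
pkatraj fixtures --sequence GADNEKAHYR --frames 20 --amplitude 1.5 --seed 21 --out fix
pkatraj predict  --topology fix/topology.pdb --trajectory fix/trajectory.pdb \
                 --engine mock --workers 2 --timestep-ps 100 --out run
pkatraj analyze  --pka run/mock_pka.csv --ph 7.4 --width 1.0 --out run
```

`predict` reports `wrote 20 frames x 6 residues` and stores the wide CSV
`run/mock_pka.csv` (first column `time_ps`, one column per residue) plus the
buried-ratio table and a failure manifest. `analyze` prints the per-residue
summary:

```
 residue      mean       sd       min       max  model_pka  delta_from_model
 ASP 3 A  4.817878 0.025411  4.782526  4.854400        3.8          1.017878
 GLU 5 A  4.856301 0.010623  4.842998  4.872813        4.5          0.356301
 LYS 6 A 10.826676 0.021847 10.796041 10.857802       10.5          0.326676
 HIS 8 A  7.443029 0.010535  7.428141  7.457943        6.5          0.943029
 TYR 9 A 11.330303 0.004125 11.324554 11.336227       10.0          1.330303
ARG 10 A 14.224834 0.052359 14.151262 14.299343       12.5          1.724834
```

`mean` is the trajectory average of each residue's predicted pKa;
`delta_from_model` is its shift from the engine's model value (for the mock
engine this is 0.1 × the residue's mean distance from the backbone centroid,
so peripheral residues shift most). `HIS 8 A` sits near pH 7.4 and is the
residue `protonation_flags.csv` lists with fraction 1.0 — for a real system
this is the signal that both protonation states are populated.

Clustering and structure mapping continue from the same tables:

```sh
pkatraj cluster --pka run/mock_pka.csv --residues "ASP 3 A" "GLU 5 A" "HIS 8 A" \
                --method kmedoids --grid "{n_clusters: [2, 3, 4]}" --seed 1 \
                --topology fix/topology.pdb --trajectory fix/trajectory.pdb \
                --timestep-ps 100 --out run
pkatraj map --pka run/mock_pka.csv --topology fix/topology.pdb --mode delta --out run
```

`cluster` prints `kmedoids: 2 clusters, 0 noise frames, silhouette 0.666`
(the grid search selected k = 2 by mean silhouette; the sinusoidal motion
yields two environment states), writes `labels.csv` and
`silhouette_scores.csv`, and extracts one medoid structure per cluster
(`cluster0_frame3.pdb`, `cluster1_frame12.pdb`). `map` writes
`map_delta.pdb`, whose B-factor column carries each residue's Δ from model,
and `map_delta.pml`, which renders it as a blue–white–red spectrum centered
at zero.

The same functionality is available as a library (`import pkatraj`); see the
docstrings of `run_prediction_pipeline`, `correlation_scan`, `grid_search`
and `write_annotated_structure`, and `docs/methods.md` for the underlying
models and conventions.

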