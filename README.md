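# disteval

Scoring and visualization of predicted inter-residue **contacts**,
**real-valued distance maps**, and **binned distograms** against a true
protein structure.

Supported prediction inputs:

* CASP RR text files — the classic 5-column format and the RMODE 1 / RMODE 2
  header variants (RMODE 2 carries per-bin probabilities over the ten
  standardized distance bins `[0,4), [4,6), ..., [18,20), [20,inf)` Å),
* real-valued Cβ distance maps as square `.npy` (or whitespace text) matrices,
* distogram bundles (`.npz` or `.tgz` archives holding an `L×L×B`
  pair-probability tensor).

True structures are standard PDB files; the representative atom is Cβ with a
Cα fallback (always Cα for glycine). Residue indices are 1-based and only the
upper triangle of any matrix is ever consulted.

## Metrics

With a structure, `evaluate` reports (each with the pair count it used):

* MAE / RMSE of long and of medium+long distances, restricted to pairs whose
  true distance is ≤ 20 Å,
* Pearson correlation of medium+long distances,
* Cβ-LDDT at sequence-separation thresholds 6 / 12 / 24 (inclusion radius
  15 Å, tolerances 0.5/1/2/4 Å),
* precision of top-L/5 and top-L predicted contacts for long and medium+long
  ranges (contact = true distance < 8 Å; L = min(sequence length, valid
  residues)).

Separation classes: local `|i−j|<6`, short `6–11`, medium `12–23`, long `≥24`.
Distograms are flattened to distances via the midpoint of the most-confident
bin, and reduced to contact confidences as the probability mass below 8 Å.
Undefined metrics (empty pair sets) are reported as `n/a`, never as 0.

## Visualization

* Combined heatmap — prediction in the upper triangle, true map in the lower,
  values standardized to [3.5, 20] Å; diagonal shows secondary-structure
  bands (helix red / strand green / coil white) or a red→green→blue sequence
  gradient; optional 45° rotation puts the diagonal vertical.
* Absolute-error heatmap when both maps are available.
* Chord diagrams (separate true and predicted) — chord width and opacity fall
  with distance (or grow with confidence); each chord takes the arc color of
  its lower-index residue.
* Three coloring schemes: `gradient`, `threshold` (flat bands split exactly
  at 8 and 12 Å), and `uniform` (perceptually uniform).

## CLI

```sh
# quantitative report (text to stdout, report.json/report.txt with --out)
disteval evaluate --pred pred.rr --pdb true.pdb --out results/

# heatmaps / chord diagrams
disteval heatmap --pred pred.npy --pdb true.pdb --scheme threshold --rotated --out viz/
disteval chord   --pred pred.npy --pdb true.pdb --out viz/
disteval heatmap --pdb true.pdb --out viz/          # true structure only

# format conversions
disteval convert --in pred_rmode2.rr --to matrix --out flat.txt
disteval convert --in pred.npy --to rr --out contacts.rr

# synthetic fixtures (structure.pdb, true.txt, pred.txt)
disteval synth --n 60 --sigma 1.0 --seed 7 --out fixtures/
```

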