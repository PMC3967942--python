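# comparanet

Comparative analysis of labeled macroscale connectomes. Given two binary or
weighted adjacency matrices over a shared parcellation (two "species"),
`comparanet` quantifies whole-network and region-wise connectivity
preservation, compares topology, detects rich-club backbones, and calibrates
everything against degree-preserving and link-weight-reshuffle null
ensembles with perturbation-based robustness checks.

## What it computes

- **Construction transforms** — symmetrize/binarize a directed matrix,
  average per-subject weighted matrices, threshold to a target edge count
  with a deterministic tie-break, split by hemisphere, measure density and
  inter-subject consistency (`comparanet.core`).
- **Cross-network similarity** — edge-set intersection ratio; per-region
  Jaccard similarity of neighbor sets (HCS); matching-index matrices with
  both endpoints excluded from the neighbor sets, and their row-wise Pearson
  correlation across networks (HMIS); cosine-based weighted variants
  (`comparanet.similarity`).
- **Topology** — betweenness (lengths 1/weight when weighted), eigenvector
  centrality, clustering (Onnela form when weighted), cross-network Spearman
  correlation, mean+1 std hub flagging (`comparanet.topology`).
- **Rich clubs** — binary coefficient phi(k) = 2 E_>k / (N_>k (N_>k − 1))
  with strict degree > k; weighted coefficient dividing by the sum of the
  E_>k largest weights network-wide; null-normalized curves with empirical
  p-values; member overlap permutation test; rich vs non-rich metric
  contrasts (`comparanet.richclub`).
- **Null models & statistics** — double-edge-swap degree-preserving
  randomization (numba-accelerated), link-and-weight reshuffle, probabilistic
  rewiring and random edge insertion perturbations, empirical z/p with the
  (1 + count)/(1 + n) convention, Bonferroni and Benjamini–Hochberg
  correction (`comparanet.nullmodels`).
- **Synthetic data** — the four-node toy pair, planted-overlap connectome
  pairs with preserved/rewired regions, and multi-subject weighted matrices
  (`comparanet.synthetic`).
- **Pipeline** — whole-brain binary and hemisphere-wise weighted arms,
  TSV reports plus a JSON run manifest (`comparanet.pipeline`).

Every random step is driven by a single integer seed; a (config, seed) pair
fully determines every number in a report.

## File formats

All plain text, tab-separated:

- **dense matrix** — header row and leading column of region labels, square.
- **edge list** — three columns `label_i  label_j  weight`, undirected
  (symmetric duplicates must agree; directed matrices use the dense format).
- **region table** — columns `label`, `hemisphere` (L/R), `lobe_class`.

## CLI

```bash
# write the four-node toy pair
comparanet toy-fig1d --out toy/

# generate a planted pair from a YAML spec
comparanet simulate --spec pairspec.yaml --out sim/

# run the full whole-brain binary analysis
comparanet run --config cfg.yaml --arm whole_brain_binary \
    --seed 1 --n-null 1000 --out report/
```

A config is a flat YAML document (`species_a`, `species_b` (path or list of
subject paths), `region_table`, `arm`, `n_null`, `alpha`, `correction`,
`seed`, optional `perturbations`). CLI flags override config keys.

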