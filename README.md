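# fluctcorr

Fluctuation-based analysis of molecular-dynamics trajectories:

* **stiffness** — pairwise effective spring constants
  `k_ij = kB·T / ⟨|ΔR_i − ΔR_j|²⟩` (kcal/mol·Å², convertible to pN/nm),
  per-site mean and overall stiffness, state-difference maps, and a joint
  RMSF/stiffness stability classification;
* **correlation** — equal-time dot-product cross-correlation maps with
  display thresholding, plus residue-pair distance distributions;
* **ctc** — time-delayed auto/cross-correlations `C_ij(τ)` on a lag grid,
  1/e decay times, and an asymmetry-based causality scan that labels
  driver → follower site pairs (`C_ij(τ) > C_ji(τ)` at a positive lag means
  i's fluctuations carry information about j's future);
* **synthetic** — seeded Gaussian ensembles and coupled Ornstein–Uhlenbeck
  networks with exact lagged-covariance oracles (Lyapunov + matrix
  exponential), so every estimator is validated against known ground truth;
* **trajectory_io** — PDB/DCD/XTC reading via MDAnalysis, Kabsch
  superposition, mean-centred fluctuation series, RMSF, and a plain-text
  fluctuation container (TSV + JSON sidecar);
* **cli** — a `fluctcorr` command with deterministic CSV/JSON/GraphML
  artifacts and an HTML/PNG report.

## CLI quick start

Everything is exercisable end-to-end from synthetic input:

```bash
cat > chain.yml <<EOF
kind: chain        # site k drives site k+1
n_sites: 3
coupling: 0.5      # 1/ps
relax: 1.0         # 1/ps
dt: 0.05           # ps
n_steps: 100000
seed: 7
EOF

fluctcorr simulate --spec chain.yml --out run/
fluctcorr causality --fluct run/fluct.tsv --lag 1.0 --out run/   # recovers 0->1, 1->2
fluctcorr stiffness --fluct run/fluct.tsv --out run/
fluctcorr xcorr     --fluct run/fluct.tsv --out run/
fluctcorr ctc       --fluct run/fluct.tsv -i 0 -j 1 --max-lag 5.0 --out run/
fluctcorr report    --dir run/
```

For real trajectories, start from a topology + trajectory pair (times are
always user-supplied in ps; the default selection is one Cα per protein
residue plus heavy atoms of non-water, non-ion hetero residues):

```bash
fluctcorr fluct --traj traj.dcd --top top.pdb --dt 1.0 --out run/
fluctcorr rmsf  --fluct run/fluct.tsv --out run/
```

Two-state comparisons (difference maps, stability classification):

```bash
fluctcorr stiffness --fluct stateA/fluct.tsv --fluct-b stateB/fluct.tsv --out diff/
```

Exit codes: 0 success, 1 runtime/data error, 2 usage error.  Re-running any
command on identical inputs and seeds produces byte-identical CSV/JSON
artifacts.

## Notes on conventions

* Temperature defaults to 310 K; `kB = 1.98720425864e-3` kcal/(mol·K);
  1 kcal/mol·Å² = 694.7695 pN/nm (from CODATA constants).
* Delayed-correlation curves are normalized by their value at zero lag by
  default; the causality scan uses the symmetric Pearson normalization
  `C_ij(τ)/sqrt(C_ii(0)·C_jj(0))` so that uncoupled pairs (equal-time
  correlation near zero) cannot produce spurious edges.  Default scan
  thresholds: strength ≥ 0.2, asymmetry ≥ 0.1 (tunable; chosen so
  independent-site noise yields no edges at 10⁵ frames).
* The overall spring constant is exposed under two aggregations
  (mean over distinct pairs, default; mean of per-site means) — they agree
  for uniform matrices.
* The conditional (binned) lagged estimator is provided as a fidelity check
  of the direct lagged-product estimator; both estimate the same expectation
  and are tested to agree.

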