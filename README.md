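# qontour

Classically simulated quantum contouring algorithms for medical image
segmentation, built for medical physicists who want to understand what
today's quantum approaches to auto-contouring actually compute — without
access to quantum hardware or to restricted clinical data.

The package implements three quantum segmentation routes end to end,
together with the shared post-processing, evaluation metrics,
quantum-resource accounting, and a synthetic abdominal phantom generator
that stands in for restricted multi-phase liver MR data:

1. **Qutrit fuzzy network** (`qontour.qisnet`) — a self-supervised,
   quantum-inspired network that maps every pixel and its eight nearest
   neighbors to a three-level (qutrit) fuzzy state and evolves a per-pixel
   population p ∈ [0, 1] through paired rotation layers R(θ), R(−θ). The
   activation is the quantum sigmoid σ(x) = 1 / (λ_ω + e^(−ν(x−β))) with
   steepness ν swept over {0.02, 0.03, 0.04, 0.05} per case and the winner
   chosen by Dice. The final population map is binarized at the highest of
   a 4-level Otsu threshold.
2. **NAQSS + Grover search** (`qontour.grover`) — the image is encoded in
   a Normal Arbitrary Quantum Superposition State: basis state |i⟩ carries
   the pixel location, amplitude θ_i = a_i / √(Σ a²) the quantized
   intensity angle a_i = (π/2)(i−1)/(M−1), and a label qubit marks
   candidate foreground supplied by an external marker mask. Grover's
   oracle (phase flip of marked states) and diffusion (reflection about
   the mean amplitude) are applied t = round((π/2 − φ)/ω) times, with
   ω = cos⁻¹(1 − 2r/N) and φ = tan⁻¹((A₀/L₀)√(r/(N−r))); for a uniform
   start this reduces to the textbook t ≈ (π/4)√(N/r).
3. **Graph-energy cuts** (`qontour.qcuts`) — superpixels become nodes of a
   fully connected graph with Gaussian intensity-similarity edges
   w_ij = (σ√2π)⁻¹ exp(−(S_i−S_j)²/2σ²); segmentation minimizes
   E(z) = E_unary(z) + λ·E_binary(z) via the smallest-eigenvalue
   eigenvector of the corresponding quadratic form (the classical stand-in
   for a quantum annealer's ground-state search), and the relaxed labeling
   y = z∘z is thresholded to {−1, 0, +1}.

Evaluation uses the Sørensen–Dice coefficient DSC = 2|X∩Y|/(|X|+|Y|) and
the boundary Hausdorff distance. `qontour.resources` accounts for NAQSS
qubit counts (n+1 qubits for 2ⁿ pixels), classical storage, and annealer
logical-variable counts.

## Worked example

```bash
qontour generate --shape 24,24 --out-dir work --seed 3
qontour qisnet --input work/case_image.nii.gz --truth work/case_truth.nii.gz \
               --out work/pred.nii.gz
```

prints the evaluation record of the best steepness value found by the
sweep:

```json
{
  "method": "qisnet",
  "dice": 0.9797297297297297,
  "hausdorff": 1.0,
  "params": {"nu": 0.03, "table": 12},
  "case_id": ""
}
```

i.e. the network recovered the phantom's bright organ with Dice 0.98 and
a worst boundary mismatch of one voxel, and ν = 0.03 won the sweep.
Resource accounting for a full-resolution volume:

```bash
qontour resources --dims 1024,1024,72 --bit-depth 32 --superpixels 256
```

```json
{
  "n_pixels": 75497472,
  "location_qubits": 27,
  "total_qubits": 28,
  "storage_bits": 2415919104,
  "storage_megabytes": 301.989888,
  "annealer_logical_qubits": 256
}
```

— a volume needing ~2.42 Gigabits (~302 MB) classically fits in 28 qubits
under NAQSS, and a 256-superpixel graph cut needs 256 logical annealing
variables. Other subcommands: `grover`, `qcuts`, `eval`, `cohort`
(multi-method comparison with a median ± sd summary table).

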