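# miranet

**Instruction-guided unified restoration of degraded medical images.**

Restoring low-quality medical images is usually done one task at a time: one
network for accelerated-MRI reconstruction, another for low-dose-CT
denoising, a third for low-count-PET synthesis. Folding the three into one
shared network typically hurts every task (negative transfer). `miranet`
implements and tests a remedy: an **adaptive restoration core (ARC)** that
reads the corrupted input itself, infers what kind of degradation it carries,
and steers a shared U-Net accordingly — no task labels, no manual switches.

The guidance mechanism, in standard notation:

```
i_IR = Σᵢ αᵢ Dᵢ ,   α = softmax(GAP(E(x_LQ)))          (instruction)
[γ, β] = MLP(i_IR)                                      (per block)
F_mod = γ ⊙ F_orig + β                                  (channel-wise affine)
```

`E` is a compact three-stage strided CNN, `D ∈ ℝ^{256×N}` a learnable
dictionary whose columns are primitive restoration strategies, and every
encoder/decoder block of the U-Net backbone is recalibrated channel-wise by
its own MLP reading the instruction vector. Everything trains end-to-end from
the restoration loss alone.

The package is self-contained for desk-scale experiments: it ships synthetic
phantom generators with modality-distinct statistics, physics-motivated
degradation simulators (Cartesian k-space undersampling, Poisson sinogram
noise + filtered back-projection, binomial count thinning), a deterministic
multi-task trainer on a small numpy autodiff engine, PSNR/SSIM/RMSE with
paired-t-test/Bonferroni statistics, and instruction-space separation
scoring. See `docs/methods.md` for the full model and simulator description.

## Worked example

```python
import miranet as mn

# a paired low-dose PET sample from the built-in generator
img  = mn.generate_phantom(mn.PhantomSpec(modality_tag="pet_like", seed=21))
pair = mn.degrade(img, mn.DegradationSpec(kind="count_thinning", seed=9))
print(round(mn.psnr(pair.low_quality, pair.high_quality), 2))   # 20.14 dB

# train a small single-task model on a 60-image cohort
cohort = mn.generate_cohort(mn.PhantomSpec(modality_tag="pet_like"), 70, seed=11)
pairs  = [mn.degrade(im, mn.DegradationSpec(kind="count_thinning", seed=100 + i))
          for i, im in enumerate(cohort)]
ds    = mn.TaskDataset(task="count_thinning", train=pairs[:60], val=pairs[60:])
model = mn.MiraNet(mn.ModelConfig(depth=3, base_channels=16, mlp_hidden=32), seed=0)
model, hist = mn.train(model, [ds], mn.TrainingConfig(epochs=3, seed=5))
print([round(v, 2) for v in hist.val_psnr["count_thinning"]])
# [19.96, 21.25, 21.66]   <- validation PSNR climbing epoch over epoch

state = model.instruction_state(pair.low_quality)
print(state.attention.round(3))  # the inferred strategy weights α (sum to 1)
```

The numbers above are what the code prints at these exact seeds (the last
line's α depends on the trained weights). A restored slice is
`model.restore(pair.low_quality)`; metrics come from
`mn.evaluate_model(model, test_samples)`.

The same work is available from a shell:

```bash
mira simulate --config sim.yaml --out data/      # paired PNG cohort + manifest
mira train --config train.yaml --out model.npz   # archive + JSON history
mira eval --model model.npz --data data/manifest_train.json --out metrics.csv
mira embed --model model.npz --data data/manifest_train.json --out alpha.csv
mira experiment --out results/                   # the full comparison (below)
```

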