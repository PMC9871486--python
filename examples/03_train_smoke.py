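"""Train both GAN variants for a few epochs on a small phantom cohort.

Sources are 80-frame DSC slice sequences, targets are classical Tmax map
slices, both normalized to [-1, 1].  The pix2pix generator sees time as
input channels; the temp-pix2pix generator first collapses the time axis
with six strided 3D convolutions.  A few epochs are enough to watch the
validation L1 fall; expert-level map quality needs far longer training.
"""

from perfsyn.maps import compute_all_maps
from perfsyn.phantom import generate_cohort
from perfsyn.preprocess import build_dataset
from perfsyn.train import TrainConfig, train

cohort = generate_cohort(12, seed=11)
volumes = {
    pid: (ph.signal, compute_all_maps(ph).tmax, ph.brain_mask)
    for pid, ph in cohort.items()
}
dataset = build_dataset(volumes, "tmax", seed=11)
print(f"slices: train {len(dataset.train)}, val {len(dataset.val)}, test {len(dataset.test)}")

for variant, tc in (("pix2pix", None), ("temp_pix2pix", (4, 8, 16, 16, 16, 16))):
    cfg = TrainConfig(variant=variant, epochs=3, seed=1, base_channels=16,
                      n_levels=5, temporal_channels=tc)
    model, state = train(dataset, cfg)
    print(f"{variant}: validation L1 {state.val_l1[0]:.3f} -> {state.val_l1[-1]:.3f} "
          f"over {cfg.epochs} epochs "
          f"({model.generator.n_parameters():,} generator parameters)")
# Falling validation L1 shows the generators are learning the source->map
# translation; the adversarial term sharpens outputs beyond what L1 alone gives.
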