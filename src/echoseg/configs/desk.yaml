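# Desk-scale configuration: the same architecture family (L3, nested
# encoder, fused attention) with a narrow width family and 64x64 synthetic
# frames, sized so the full train/evaluate/EF pipeline runs in minutes on
# one CPU.  Training hyperparameters (lr 1e-4, batch 2, alpha 0.8) are the
# reference recipe.
model:
  in_channels: 1
  channel_widths: [24, 48, 96, 192]
  prune_level: 3
  deep_supervision: true
  attention:
    reduction_ratio: 8
    spatial_kernel: 7
    simam_lambda: 1.0e-4
  attention_mode: scbam
  nested_encoder: true
  nested_mid_factor: 1
train:
  learning_rate: 1.0e-4
  batch_size: 2
  epochs: 5
  alpha: 0.8
  prune_level: 3
synth:
  image_size: 64
  n_frames: 20
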