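# Reference network: prune level L3, nested encoder blocks, fused attention
# at every node.  Channel widths frozen by scripts/match_reference.py so the
# L3 sub-network totals 5.96 M trainable parameters and 25.74 GFLOPs for one
# 1x112x112 frame under the pinned MAC=2FLOP convention.
model:
  in_channels: 1
  channel_widths: [80, 80, 128, 256]
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
  epochs: 50
  alpha: 0.8
  prune_level: 3
synth:
  image_size: 112
  n_frames: 20
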