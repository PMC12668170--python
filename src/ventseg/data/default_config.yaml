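# Default end-to-end experiment configuration.
# "published" marks values taken from the study this package reimplements;
# "package default" marks choices made here (see docs/methods.md).

sim:
  n_patients: 10              # package default (33 in the real cohort)
  breaths_per_patient: 294    # published: mean breaths/patient
  asynchrony_fraction: 0.28   # published: PVA prevalence, training/validation set
  artifact_fraction: 0.06     # published: 6% artifact breaths
  dt_within_asynchrony: 0.5   # package default: DT vs stacked split is a free parameter
  noise_sd_flow: 1.0          # package default, L/min
  noise_sd_pressure: 0.5      # package default, cm H2O
  baseline_wander_amplitude: 0.2 # package default; small so drift-integrated
                                  # volume error stays inside the 0.05 TVe/TVi
                                  # decision margins (see docs/methods.md)
  sample_rate: 50.0           # published: 50 Hz capture
  seed: 0

segmenter:
  depth: 4                    # published: four encoder blocks
  base_filters: 8             # package default (CPU-sized; published filter counts not stated)
  kernel_size: 7              # package default
  convs_per_block: 1          # package default (CPU-sized)
  bottleneck_dilations: [1, 2, 4]  # package default
  dropout_bottleneck: 0.3     # package default
  dropout_head: 0.2           # package default
  input_len: 352              # published: 7.04 s windows
  output_len: 176             # published: central 3.52 s output span
  alpha: 0.25                 # package default focal balancing factor
  gamma: 2.0                  # package default focal focusing strength
  epsilon: 1.0e-6             # package default dice stability constant
  learning_rate: 5.0e-4       # published: AdamW initial learning rate
  weight_decay: 1.0e-2        # package default (magnitude not published)
  batch_size: 32              # published
  patience: 10                # published early-stopping patience
  min_delta: 1.0e-4           # published early-stopping minimum delta
  max_epochs: 25              # package default (CPU budget)
  threshold: 0.5              # package default event threshold (strict >)
  debounce: 5                 # package default, samples = evaluation tolerance

split: [0.8, 0.1, 0.1]        # published: by-patient train/val/test split
tolerance: 0.1                # published: evaluation tolerance window, seconds
seed: 0
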