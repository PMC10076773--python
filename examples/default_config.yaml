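connectivity: 26
diameter_max_mm: 15.0
diameter_min_mm: 3.0
dilation_kernel_shape:
- 3
- 3
- 3
include_ventricle_margin: true
k_classes: 2
kmeans_seed: 0
tissue_classes: 3
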