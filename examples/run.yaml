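# Example pipeline configuration for `gliaquant all --config examples/run.yaml`
# Any omitted key keeps its default. Seeds control every random stage.
seed: 1
n_hi: 17          # hypoxia-ischemia animals (twin controls match this count)
n_week1: 10       # of which euthanized at 1 week (rest at 2 weeks)
n_sections: 3     # triplicate sections per animal per marker
image_width: 256  # section geometry; 512 is the full-scale default
image_height: 256
bit_depth: 8
section_jitter_sd: 0.02
skip_images: false   # true: take fractions from the generator, no imaging
write_images: true   # false: quantify in memory without writing TIFFs
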