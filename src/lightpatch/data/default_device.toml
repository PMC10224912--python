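# Default patch device: tapered 100 um fiber, 280 um taper, 1 um tip,
# pulled back 15 um inside a 125 um-thick, 25 mm-diameter refractive patch.
# Media indices: air 1.0003, patch polyester (PMCL) 1.49, tissue ~1.4,
# fiber core 1.4613, fiber cladding 1.4562, light-path imaging solution 1.40.

[media]
air = 1.0003
patch = 1.49
tissue = 1.4
core = 1.4613
cladding = 1.4562
lightpath = 1.40

[taper]
tip_radius_um = 0.5
base_radius_um = 50.0
taper_length_um = 280.0
shape_exponent = 2.0

[gap]
d_um = 15.0

[slab]
thickness_um = 125.0
disk_radius_mm = 12.5
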