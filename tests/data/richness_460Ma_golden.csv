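# thermodiv v0.1.0 config_hash=07ccee8d42d6 seed=7
lat,lon,richness
-56.25,33.75,21.4
-56.25,56.25,21.4
-56.25,303.75,21.4
-56.25,326.25,21.4
-33.75,258.75,5.4
-33.75,281.25,5.4
-33.75,348.75,5.4
-11.25,168.75,0.0
-11.25,213.75,0.0
-11.25,236.25,0.0
-11.25,303.75,0.0
-11.25,326.25,0.0
11.25,146.25,0.0
11.25,191.25,0.0
11.25,258.75,0.0
11.25,281.25,0.0
33.75,168.75,5.4
33.75,213.75,5.4
33.75,236.25,5.4
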