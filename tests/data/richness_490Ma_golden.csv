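# thermodiv v0.1.0 config_hash=07ccee8d42d6 seed=7
lat,lon,richness
-56.25,11.25,0.0
-56.25,78.75,0.0
-33.75,33.75,0.0
-33.75,56.25,0.0
-33.75,258.75,0.0
-33.75,281.25,0.0
-11.25,168.75,0.0
-11.25,213.75,0.0
-11.25,236.25,0.0
-11.25,303.75,0.0
11.25,146.25,0.0
11.25,191.25,0.0
11.25,258.75,0.0
11.25,281.25,0.0
33.75,168.75,0.0
33.75,213.75,0.0
33.75,236.25,0.0
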