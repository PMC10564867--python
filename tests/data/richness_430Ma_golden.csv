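# thermodiv v0.1.0 config_hash=07ccee8d42d6 seed=7
lat,lon,richness
-56.25,33.75,20.2
-56.25,56.25,20.2
-33.75,258.75,18.8
-33.75,281.25,18.8
-33.75,303.75,18.8
-33.75,326.25,18.8
-11.25,168.75,5.4
-11.25,213.75,5.4
-11.25,236.25,5.4
-11.25,348.75,5.4
11.25,146.25,5.4
11.25,191.25,5.4
11.25,258.75,5.4
11.25,281.25,5.4
11.25,303.75,5.4
11.25,326.25,5.4
33.75,168.75,18.8
33.75,213.75,18.8
33.75,236.25,18.8
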