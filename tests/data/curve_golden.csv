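# thermodiv v0.1.0 config_hash=07ccee8d42d6 seed=7
age,median,std,scenario,domain
490.0,0.0,0.0,proxy-cooling,global-shelf
460.0,5.4,8.188431810332512,proxy-cooling,global-shelf
430.0,5.4,6.857763459582871,proxy-cooling,global-shelf
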