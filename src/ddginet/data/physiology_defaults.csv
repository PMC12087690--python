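# ddginet physiology defaults, version 1
# Reference: 73 kg adult male. Volumes scale linearly with body weight;
# flows scale with (BW/73)^0.75. Flows are perfusion rates of the lumped
# minimal whole-body topology (gut wall, liver via portal vein + hepatic
# artery, one peripheral tissue); "central" is plasma plus rapidly
# equilibrating tissue and carries no perfusion entry of its own.
organ,volume_l_per_kg,flow_l_per_h_at_ref
gut_wall,0.0151,50.0
liver,0.0247,20.0
central,0.2100,0.0
peripheral,0.5500,200.0
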