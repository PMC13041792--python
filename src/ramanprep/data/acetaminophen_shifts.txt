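# Acetaminophen certified Raman shift library (cm-1), one per line
213.3
329.2
390.9
465.1
504.0
651.6
710.8
797.2
834.5
857.9
968.7
1105.5
1168.5
1236.8
1278.5
1323.9
1371.5
1561.5
1648.4
2931.1
3064.6
3326.6
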