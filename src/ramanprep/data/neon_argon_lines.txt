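# Ne-Ar emission reference library: absolute wavenumber (cm-1), one per line
9677.994
10220.246
10346.162
10354.336
10474.045
10488.601
10571.707
10609.652
10668.590
10690.362
10722.124
10751.705
10781.067
10840.696
10867.486
10930.551
10961.343
11125.253
11211.391
11279.349
11294.496
11384.659
11400.351
11488.825
11518.190
11536.767
11554.843
11581.245
11639.736
11666.774
11703.161
11735.106
11771.132
11815.638
11869.929
11878.699
11893.138
11936.579
11953.501
12047.714
12097.633
12107.446
12290.433
12317.470
12322.388
12340.057
12372.471
12476.933
12490.382
12581.497
12589.416
12947.060
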