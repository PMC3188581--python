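name	start	end	annotation
SD1	242	261	P-loop region
SD2	262	278	-
SD3	279	291	alphaC-helix
SD4	292	309	-
SD5	310	335	hinge region
SD6A	336	356	-
SD6B	357	374	catalytic loop
SD7	375	393	activation loop
SD8	394	416	P+1 loop
SD9	417	438	-
SD10	439	461	-
SD11	462	480	-
SD12	481	498	-
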