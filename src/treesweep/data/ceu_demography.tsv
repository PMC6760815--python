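epoch_start_gen	Ne
0	164500
100	21700
205	2590
920	1861
2040	14474
5920	7310
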