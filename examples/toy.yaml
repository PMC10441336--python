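# Synthetic three-brain cohort: two PicoPLEX individuals at 250 kb bins,
# one PTA control, with planted 3 Mb gains and 2.5 Mb losses.
cohort:
  genome: [[chr1, 50000000], [chr2, 50000000], [chr3, 40000000],
           [chr4, 40000000], [chr5, 30000000]]
  bin_size: 250000
  cells:
    - {individual: MSA1, method: picoplex, n: 8}
    - {individual: MSA2, method: picoplex, n: 6}
    - {individual: Control, method: pta, n: 6}
  cnv_menu:
    - {size: 3000000, cn: 3, frequency: 0.4}
    - {size: 2500000, cn: 1, frequency: 0.3}
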