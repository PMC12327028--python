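# Published per-day multiparametric vessel series (MC903 atopic-dermatitis
# mouse-ear time course, days 0-14: normal -> modeling -> treating), with the
# published "average rate of change" in the final column.
# Row labels are preserved exactly as printed; note the 2D VS/VSD rows appear
# label-swapped (the 2D "VSD" row holds skeleton counts, the 2D "VS" row holds
# densities) -- see docs/methods.md.
dims,parameter,day0,day2,day4,day6,day8,day10,day12,day14,printed_rate
3D,VA,278504,234977,317641,434710,495952,605974,276343,210057,0.289
3D,VS,7968,10078,10451,12230,18075,14495,9430,5560,0.273
3D,VAD,0.0754,0.0790,0.0844,0.1007,0.1569,0.1398,0.0677,0.0604,0.229
3D,VSD,0.00216,0.00277,0.00282,0.00283,0.00366,0.00334,0.00231,0.00160,0.186
2D,VA,35553,38541,41029,47283,65793,52166,43737,25485,0.211
2D,VSD,6720,6721,8066,8499,10134,8459,7020,4248,0.168
2D,VS,0.2743,0.2974,0.3166,0.3648,0.5077,0.4025,0.3375,0.1966,0.211
2D,VAD,0.05185,0.05186,0.06224,0.06558,0.07819,0.06527,0.05417,0.03278,0.169
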