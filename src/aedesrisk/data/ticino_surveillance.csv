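year,ovitraps_analyzed,ovitraps_established,cells_observed,cells_established
2004,57,3,25,3
2005,189,0,76,0
2006,235,5,82,3
2007,292,23,101,16
2008,466,94,163,44
2009,1241,144,887,106
2010,1342,181,973,144
2011,1357,265,983,211
2012,1361,580,1017,466
2013,1389,524,1108,456
2014,1022,463,925,425
2015,1031,793,928,727
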