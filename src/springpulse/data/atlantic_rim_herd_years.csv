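herd,year,n,individual_start,herd_start,max_simultaneous,median_displacement_km
NAR,2005,7,4/9,4/23,6,32
NAR,2006,8,4/3,4/21,5,28
NAR,2008,12,4/30,5/16,10,26
NAR,2009,8,3/18,5/8,7,23
NAR,2010,1,5/5,5/5,1,16
NAR,2015,11,3/16,3/27,5,34
NAR,2016,14,4/4,5/3,10,34
NAR,2017,16,3/13,4/17,9,21
NAR,2018,15,4/11,4/19,9,24
SAR,2005,21,4/1,4/16,16,37
SAR,2006,20,3/27,4/22,15,36
SAR,2008,9,3/17,5/15,9,30
SAR,2009,19,2/28,5/6,15,35
SAR,2010,11,3/12,5/8,9,56
SAR,2015,24,1/20,4/7,16,56
SAR,2016,20,2/26,4/22,15,68
SAR,2017,18,2/18,4/11,15,63
SAR,2018,19,2/13,4/22,15,46
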