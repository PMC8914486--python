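year,index
2011,400.258
2012,414.924
2013,425.134
2014,435.292
2015,446.752
2016,463.675
2017,475.319
2018,484.715
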