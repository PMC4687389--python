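scan_id,raw_air,raw_reference,raw_range,target_air,target_range
N,11988,21532,9543,13192,8635
A,13415,21113,7699,13192,8635
B,14174,22835,8661,13192,8635
C,14335,23019,8685,15206,8278
D,16078,23950,7872,15206,8278
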