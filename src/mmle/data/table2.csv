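model,stratum,sex,weighted_le,le_lo,le_hi,mmle,mmle_lo,mmle_hi,pct_mm
M1,overall,male,37.6,36.7,38.4,9.8,9.0,10.6,26
M1,overall,female,44.3,43.4,45.1,17.3,16.4,18.1,39
M2,African,male,36.7,35.8,37.6,9.0,8.2,9.7,25
M2,African,female,43.6,42.7,44.5,16.5,15.6,17.4,38
M2,Asian/Indian,male,44.1,38.5,49.7,13.4,8.5,18.4,30
M2,Asian/Indian,female,50.3,45.5,55.1,21.5,16.1,26.9,43
M2,Coloured,male,38.5,36.9,40.1,12.0,10.5,13.5,31
M2,Coloured,female,45.9,44.3,47.5,20.3,18.6,22.0,44
M2,white,male,46.5,43.7,49.3,13.1,10.5,15.7,28
M2,white,female,52.1,49.8,54.5,20.6,17.7,23.5,40
M3,less than secondary,male,35.3,34.1,36.4,9.9,9.0,10.9,28
M3,less than secondary,female,42.6,41.5,43.6,17.8,16.7,18.9,42
M3,secondary,male,37.6,36.4,38.9,9.3,8.2,10.3,25
M3,secondary,female,44.3,43.0,45.6,16.7,15.4,18.0,38
M3,post-secondary,male,46.4,44.1,48.7,12.6,10.6,14.7,27
M3,post-secondary,female,51.9,50.0,53.8,19.8,17.5,22.0,38
M4,African x less than secondary,male,35.5,34.3,36.7,9.7,8.7,10.7,27
M4,African x less than secondary,female,42.8,41.6,43.9,17.6,16.5,18.8,41
M4,African x secondary or more,male,37.2,35.9,38.4,8.2,7.2,9.2,22
M4,African x secondary or more,female,43.7,42.4,45.0,15.3,14.0,16.6,35
M4,Coloured x less than secondary,male,35.0,33.1,36.9,11.1,9.4,12.7,32
M4,Coloured x less than secondary,female,42.9,40.9,44.8,19.5,17.5,21.6,45
M4,Coloured x secondary or more,male,45.3,42.1,48.4,16.0,13.0,18.9,35
M4,Coloured x secondary or more,female,51.6,49.1,54.2,24.0,21.0,26.9,47
M4,white x less than secondary,male,44.8,33.9,55.7,19.2,8.3,30.2,43
M4,white x less than secondary,female,51.6,43.0,60.2,28.2,17.7,38.8,55
M4,white x secondary or more,male,46.1,43.1,49.0,13.0,10.2,15.7,28
M4,white x secondary or more,female,51.7,49.2,54.2,20.5,17.4,23.5,40
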