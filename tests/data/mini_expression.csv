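,feat0000,feat0001,feat0002,feat0003,feat0004,feat0005,feat0006,feat0007,feat0008,feat0009,feat0010,feat0011
S0000,13.0,2.0,14.0,17.0,40.0,0.0,0.0,73.0,57.0,9.0,8.0,9.0
S0001,13.0,6.0,13.0,19.0,2.0,1.0,9.0,25.0,1.0,2.0,13.0,13.0
S0002,4.0,6.0,46.0,6.0,104.0,2.0,6.0,23.0,42.0,13.0,8.0,32.0
S0003,24.0,1.0,18.0,9.0,100.0,4.0,0.0,29.0,63.0,4.0,13.0,27.0
S0004,7.0,2.0,7.0,10.0,33.0,0.0,1.0,5.0,4.0,4.0,13.0,14.0
S0005,24.0,7.0,4.0,3.0,53.0,1.0,1.0,51.0,49.0,3.0,21.0,8.0
S0006,14.0,8.0,25.0,6.0,6.0,0.0,9.0,31.0,3.0,10.0,10.0,20.0
S0007,8.0,2.0,38.0,11.0,81.0,5.0,4.0,26.0,18.0,6.0,9.0,19.0
S0008,0.0,8.0,12.0,9.0,5.0,1.0,11.0,40.0,6.0,2.0,21.0,8.0
S0009,6.0,5.0,22.0,14.0,5.0,4.0,39.0,71.0,2.0,3.0,19.0,13.0
S0010,13.0,0.0,11.0,7.0,1.0,2.0,21.0,9.0,1.0,0.0,15.0,6.0
S0011,19.0,2.0,10.0,23.0,37.0,2.0,2.0,40.0,23.0,8.0,10.0,42.0
S0012,8.0,0.0,10.0,10.0,4.0,0.0,5.0,72.0,1.0,0.0,13.0,12.0
S0013,77.0,7.0,9.0,14.0,6.0,2.0,17.0,44.0,7.0,2.0,54.0,29.0
S0014,17.0,2.0,15.0,5.0,3.0,4.0,8.0,22.0,3.0,1.0,18.0,32.0
S0015,18.0,5.0,22.0,9.0,0.0,4.0,10.0,75.0,6.0,21.0,25.0,18.0
S0016,20.0,5.0,6.0,14.0,42.0,3.0,4.0,62.0,37.0,15.0,24.0,34.0
S0017,18.0,2.0,8.0,6.0,22.0,0.0,0.0,13.0,59.0,14.0,17.0,15.0
S0018,22.0,5.0,19.0,11.0,4.0,3.0,9.0,14.0,2.0,1.0,16.0,32.0
S0019,26.0,12.0,9.0,3.0,6.0,1.0,10.0,20.0,3.0,9.0,28.0,34.0
S0020,14.0,3.0,29.0,2.0,20.0,1.0,2.0,13.0,25.0,4.0,20.0,11.0
S0021,19.0,10.0,17.0,14.0,4.0,1.0,14.0,13.0,3.0,6.0,57.0,10.0
S0022,6.0,2.0,6.0,8.0,28.0,0.0,1.0,38.0,9.0,2.0,8.0,5.0
S0023,20.0,7.0,12.0,13.0,124.0,2.0,1.0,13.0,28.0,7.0,49.0,6.0
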