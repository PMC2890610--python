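derivative,I,IIa,IIb,III,IVa,IVb
D01,-13.2 ± 1.8,5.9 ± 1.5,-2.8 ± 1.6,1.1 ± 1.7,5.5 ± 2.6,-16.9 ± 2.7
D02,-9.6 ± 3.3,-24.8 ± 1.6,-7.9 ± 2.2,1.4 ± 2.2,15.1 ± 4.0,-5.4 ± 3.9
D03,-19.9 ± 6.2,-10.7 ± 3.9,-17.0 ± 3.9,6.6 ± 2.4,-9.5 ± 4.7,-20.7 ± 7.6
D04,-30.0 ± 4.8,-8.3 ± 2.1,-7.0 ± 3.9,2.2 ± 4.0,-8.2 ± 4.2,-10.0 ± 3.4
D05,-13.8 ± 3.4,-11.5 ± 2.0,3.5 ± 2.4,5.0 ± 1.7,-7.0 ± 3.5,-13.9 ± 2.1
D06,8.6 ± 4.0,4.8 ± 2.1,20.0 ± 1.7,-4.3 ± 1.3,8.1 ± 2.6,-12.7 ± 5.7
D07,-2.8 ± 0.8,-9.8 ± 1.7,2.6 ± 1.7,1.2 ± 1.6,1.8 ± 2.3,-10.2 ± 1.9
D08,-2.5 ± 2.7,-7.8 ± 1.6,1.1 ± 4.5,2.2 ± 3.0,3.5 ± 3.1,-16.5 ± 6.2
D09,2.9 ± 5.8,-7.0 ± 1.9,0.1 ± 3.3,0.3 ± 4.4,14.1 ± 3.7,4.7 ± 6.3
D10,-10.6 ± 4.6,-13.2 ± 3.0,-4.9 ± 4.3,-21.7 ± 1.8,-15.9 ± 4.1,-15.8 ± 6.1
D11,37.6 ± 1.6,-0.6 ± 0.8,10.7 ± 1.7,13.1 ± 0.3,3.2 ± 3.4,-19.1 ± 1.6
D12,-15.6 ± 1.6,-23.2 ± 2.1,-4.1 ± 1.9,-15.1 ± 1.6,-2.8 ± 2.7,-30.4 ± 3.3
D13,0.1 ± 2.3,-5.2 ± 3.4,9.7 ± 1.5,2.3 ± 2.2,-3.7 ± 2.3,-18.1 ± 3.6
D14,-0.1 ± 4.0,-11.0 ± 1.9,0.6 ± 1.5,26.3 ± 1.9,26.5 ± 2.7,-20.0 ± 6.1
D15,12.4 ± 3.3,-3.5 ± 1.6,-1.4 ± 0.8,6.3 ± 1.6,-4.3 ± 2.3,-4.4 ± 3.2
D16,-2.8 ± 4.2,-3.9 ± 0.9,5.5 ± 1.8,-9.1 ± 3.8,-9.9 ± 3.5,-15.5 ± 2.2
D17,7.8 ± 5.1,-1.3 ± 1.4,3.1 ± 4.3,1.9 ± 1.5,26.1 ± 3.6,-6.6 ± 3.8
D18,-2.1 ± 2.9,-1.1 ± 3.4,3.3 ± 2.8,16.8 ± 1.4,-5.6 ± 1.9,-10.1 ± 2.3
D19,-10.3 ± 3.8,3.4 ± 3.2,-11.0 ± 2.3,-0.2 ± 1.5,-15.1 ± 3.2,-6.1 ± 5.1
D20,-1.7 ± 5.1,0.9 ± 1.7,10.6 ± 3.5,7.8 ± 1.8,-6.4 ± 3.9,-8.4 ± 3.7
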