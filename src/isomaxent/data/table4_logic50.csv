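compound,A549,HeLa,MCF-7,CEM,M010B,M006X
D00,-6.46 ± 0.04,-6.86 ± 0.05,-7.83 ± 0.06,-8.03 ± 0.04,-7.70 ± 0.05,-8.35 ± 0.30
D01,-5.29 ± 0.11,N/A,-5.25 ± 0.10,N/A,N/A,N/A
D02,-5.89 ± 0.06,-6.48 ± 0.13,-6.32 ± 0.11,-6.65 ± 0.08,N/A,N/A
D03,-5.07 ± 0.04,-5.41 ± 0.13,-5.23 ± 0.07,-5.39 ± 0.11,N/A,N/A
D04,-5.09 ± 0.06,-5.46 ± 0.13,-5.25 ± 0.08,-5.51 ± 0.13,-5.22 ± 0.07,-6.12 ± 0.04
D05,-7.83 ± 0.10,-7.89 ± 0.06,-7.42 ± 0.13,-8.64 ± 0.08,-7.94 ± 0.03,-8.41 ± 0.08
D06,-7.80 ± 0.07,-7.68 ± 0.09,-7.50 ± 0.13,-8.48 ± 0.09,-7.49 ± 0.13,-7.98 ± 0.03
D07,-7.66 ± 0.08,-8.25 ± 0.09,-8.10 ± 0.05,-8.49 ± 0.10,N/A,N/A
D08,-6.52 ± 0.13,-6.66 ± 0.11,-6.17 ± 0.07,-6.76 ± 0.07,-6.60 ± 0.13,-7.12 ± 0.06
D09,-6.66 ± 0.09,-7.35 ± 0.09,-7.10 ± 0.04,-7.46 ± 0.08,-6.74 ± 0.08,-7.47 ± 0.09
D10,-6.47 ± 0.12,-7.23 ± 0.09,-7.05 ± 0.04,-7.45 ± 0.09,-6.74 ± 0.08,-7.40 ± 0.09
D11,-5.77 ± 0.10,-6.17 ± 0.07,-6.27 ± 0.08,-6.45 ± 0.08,-5.66 ± 0.10,-6.42 ± 0.09
D12,-4.51 ± 0.31,-5.33 ± 0.14,-5.19 ± 0.09,-5.50 ± 0.10,-4.90 ± 0.09,-5.67 ± 0.12
D13,-4.95 ± 0.07,-5.33 ± 0.11,-5.22 ± 0.08,-5.53 ± 0.11,-5.20 ± 0.08,-5.44 ± 0.13
D14,N/A,N/A,N/A,N/A,N/A,N/A
D15,-6.00 ± 0.04,-6.43 ± 0.14,-6.30 ± 0.12,-6.46 ± 0.09,-6.39 ± 0.11,-6.47 ± 0.12
D16,-6.23 ± 0.08,-6.22 ± 0.09,-6.35 ± 0.12,-6.57 ± 0.11,-6.38 ± 0.14,-6.45 ± 0.13
D17,-7.38 ± 0.14,-7.77 ± 0.09,-7.37 ± 0.11,-8.47 ± 0.13,-7.65 ± 0.10,-8.34 ± 0.11
D18,-8.50 ± 0.12,-8.45 ± 0.11,-8.31 ± 0.13,-8.29 ± 0.10,N/A,N/A
D19,-8.37 ± 0.11,-8.47 ± 0.14,-8.28 ± 0.10,-8.64 ± 0.09,-8.27 ± 0.12,-8.83 ± 0.08
D20,-8.76 ± 0.10,-8.66 ± 0.13,-8.71 ± 0.11,-8.55 ± 0.09,-8.51 ± 0.14,N/A
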