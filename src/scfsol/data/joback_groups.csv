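group,tc,pc,tb,n_atoms
-CH3,0.0141,-0.0012,23.58,4
>CH2,0.0189,0.0000,22.88,3
>CH-,0.0164,0.0020,21.74,2
>C<,0.0067,0.0043,18.25,1
=CH2,0.0113,-0.0028,18.18,3
=CH-,0.0129,-0.0006,24.96,2
=C<,0.0117,0.0011,24.14,1
ring>CH2,0.0100,0.0025,27.15,3
ring>CH-,0.0122,0.0004,21.78,2
ring>C<,0.0042,0.0061,21.32,1
ring=CH-,0.0082,0.0011,26.73,2
ring=C<,0.0143,0.0008,31.01,1
-OH (alcohol),0.0741,0.0112,92.88,2
-O- (nonring),0.0168,0.0015,22.42,1
>C=O (nonring),0.0380,0.0031,76.75,2
-CHO,0.0379,0.0030,72.24,3
-COOH,0.0791,0.0077,169.09,4
-COO-,0.0481,0.0005,81.10,3
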