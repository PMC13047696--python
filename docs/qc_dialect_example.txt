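 Entering Gaussian System, Link 0
 ---------------------------------------------------------------------
 label=example-EtOH+ role=protonated_monomer site=1 sigma=1 gelec=1
 ---------------------------------------------------------------------
 Charge =  1 Multiplicity = 1
 Stoichiometry    C2H5O(1+)
                         Standard orientation:
 ---------------------------------------------------------------------
 Center     Atomic      Atomic             Coordinates (Angstroms)
 Number     Number       Type             X           Y           Z
 ---------------------------------------------------------------------
      1          6           0      -0.225430    0.102375    0.088314
      2          6           0       1.569231   -0.069793    0.298326
      3          1           0       0.288501    1.611325    0.090276
      4          1           0       1.613068    1.433353   -0.218942
      5          1           0       0.132893    0.015213    1.386145
      6          1           0       1.491501    0.233693    1.760426
      7          1           0      -0.085323    1.542918    1.393122
      8          8           0       1.556580    1.402747    1.434971
 ---------------------------------------------------------------------
 Rotational constants (GHZ):        0.428460        0.306715        0.038036
 SCF Done:  E(RM062X) =    -999.960972565     A.U. after   11 cycles
 Harmonic frequencies (cm**-1):
 Frequencies --     39.5026     87.3509    146.5419
 Frequencies --    172.1781    639.5250    966.1599
 Frequencies --   1908.8704   1916.3787   2135.0261
 Frequencies --   2240.2571   2561.3531   2561.9044
 Frequencies --   2852.0477   2861.0118   3005.1928
 Frequencies --   3025.2309   3197.2619   3274.7013
 Zero-point correction=                           0.076525 (Hartree/Particle)
 Molecular mass:     45.03404 amu.
 Normal termination of Gaussian 16.
 --Link1--
 SCF Done:  E(RM062X) =    -999.965515717     A.U. after    1 cycles
 Normal termination of Gaussian 16.
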