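ATOM      1  N  ALA A   1      -4.945  -2.362   0.146  1.00  0.00           N  
ATOM      2  CA ALA A   1      -3.713  -2.318  -0.632  1.00  0.00           C  
ATOM      3  C  ALA A   1      -2.491  -2.214   0.276  1.00  0.00           C  
ATOM      4  O  ALA A   1      -2.475  -1.431   1.223  1.00  0.00           O  
ATOM      5  CB ALA A   1      -3.743  -1.141  -1.609  1.00  0.00           C  
ATOM      6  N  ALA A   2      -1.469  -3.010  -0.023  1.00  0.00           N  
ATOM      7  CA ALA A   2      -0.242  -3.009   0.765  1.00  0.00           C  
ATOM      8  C  ALA A   2       0.987  -3.128  -0.130  1.00  0.00           C  
ATOM      9  O  ALA A   2       1.021  -3.943  -1.049  1.00  0.00           O  
ATOM     10  CB ALA A   2      -0.263  -4.151   1.783  1.00  0.00           C  
ATOM     11  N  ALA A   3       1.995  -2.307   0.147  1.00  0.00           N  
ATOM     12  CA ALA A   3       3.228  -2.318  -0.632  1.00  0.00           C  
ATOM     13  C  ALA A   3       4.449  -2.151   0.267  1.00  0.00           C  
ATOM     14  O  ALA A   3       4.464  -1.303   1.156  1.00  0.00           O  
ATOM     15  CB ALA A   3       3.198  -1.213  -1.690  1.00  0.00           C  
ATOM     16  N  ALA A   4       4.945   2.438  -0.146  1.00  0.00           N  
ATOM     17  CA ALA A   4       3.713   2.482   0.632  1.00  0.00           C  
ATOM     18  C  ALA A   4       2.491   2.586  -0.276  1.00  0.00           C  
ATOM     19  O  ALA A   4       2.475   3.369  -1.223  1.00  0.00           O  
ATOM     20  CB ALA A   4       3.743   3.659   1.609  1.00  0.00           C  
ATOM     21  N  ALA A   5       1.469   1.790   0.023  1.00  0.00           N  
ATOM     22  CA ALA A   5       0.242   1.791  -0.765  1.00  0.00           C  
ATOM     23  C  ALA A   5      -0.987   1.672   0.130  1.00  0.00           C  
ATOM     24  O  ALA A   5      -1.021   0.857   1.049  1.00  0.00           O  
ATOM     25  CB ALA A   5       0.263   0.649  -1.783  1.00  0.00           C  
ATOM     26  N  ALA A   6      -1.995   2.493  -0.147  1.00  0.00           N  
ATOM     27  CA ALA A   6      -3.228   2.482   0.632  1.00  0.00           C  
ATOM     28  C  ALA A   6      -4.449   2.649  -0.267  1.00  0.00           C  
ATOM     29  O  ALA A   6      -4.464   3.497  -1.156  1.00  0.00           O  
ATOM     30  CB ALA A   6      -3.198   3.587   1.690  1.00  0.00           C  
END
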