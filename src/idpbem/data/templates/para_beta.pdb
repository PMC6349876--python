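ATOM      1  N  ALA A   1      -4.774  -2.320   0.080  1.00  0.00           N  
ATOM      2  CA ALA A   1      -3.553  -2.259  -0.714  1.00  0.00           C  
ATOM      3  C  ALA A   1      -2.321  -2.133   0.177  1.00  0.00           C  
ATOM      4  O  ALA A   1      -2.127  -1.118   0.842  1.00  0.00           O  
ATOM      5  CB ALA A   1      -3.615  -1.087  -1.695  1.00  0.00           C  
ATOM      6  N  ALA A   2      -1.493  -3.172   0.184  1.00  0.00           N  
ATOM      7  CA ALA A   2      -0.279  -3.179   0.992  1.00  0.00           C  
ATOM      8  C  ALA A   2       0.964  -3.314   0.119  1.00  0.00           C  
ATOM      9  O  ALA A   2       1.185  -4.350  -0.505  1.00  0.00           O  
ATOM     10  CB ALA A   2      -0.329  -4.315   2.016  1.00  0.00           C  
ATOM     11  N  ALA A   3       1.772  -2.260   0.082  1.00  0.00           N  
ATOM     12  CA ALA A   3       2.994  -2.259  -0.714  1.00  0.00           C  
ATOM     13  C  ALA A   3       4.225  -2.067   0.166  1.00  0.00           C  
ATOM     14  O  ALA A   3       4.419  -1.005   0.753  1.00  0.00           O  
ATOM     15  CB ALA A   3       2.933  -1.163  -1.780  1.00  0.00           C  
ATOM     16  N  ALA A   4      -4.774   2.480   0.080  1.00  0.00           N  
ATOM     17  CA ALA A   4      -3.553   2.541  -0.714  1.00  0.00           C  
ATOM     18  C  ALA A   4      -2.321   2.667   0.177  1.00  0.00           C  
ATOM     19  O  ALA A   4      -2.127   3.682   0.842  1.00  0.00           O  
ATOM     20  CB ALA A   4      -3.615   3.713  -1.695  1.00  0.00           C  
ATOM     21  N  ALA A   5      -1.493   1.628   0.184  1.00  0.00           N  
ATOM     22  CA ALA A   5      -0.279   1.621   0.992  1.00  0.00           C  
ATOM     23  C  ALA A   5       0.964   1.486   0.119  1.00  0.00           C  
ATOM     24  O  ALA A   5       1.185   0.450  -0.505  1.00  0.00           O  
ATOM     25  CB ALA A   5      -0.329   0.485   2.016  1.00  0.00           C  
ATOM     26  N  ALA A   6       1.772   2.540   0.082  1.00  0.00           N  
ATOM     27  CA ALA A   6       2.994   2.541  -0.714  1.00  0.00           C  
ATOM     28  C  ALA A   6       4.225   2.733   0.166  1.00  0.00           C  
ATOM     29  O  ALA A   6       4.419   3.795   0.753  1.00  0.00           O  
ATOM     30  CB ALA A   6       2.933   3.637  -1.780  1.00  0.00           C  
END
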