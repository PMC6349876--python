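ATOM      1  N  ALA A   1      -1.948  -2.769  -4.172  1.00  0.00           N  
ATOM      2  CA ALA A   1      -1.512  -1.381  -4.274  1.00  0.00           C  
ATOM      3  C  ALA A   1      -1.661  -0.656  -2.940  1.00  0.00           C  
ATOM      4  O  ALA A   1      -0.748   0.034  -2.493  1.00  0.00           O  
ATOM      5  CB ALA A   1      -2.306  -0.653  -5.360  1.00  0.00           C  
ATOM      6  N  ALA A   2      -2.820  -0.820  -2.311  1.00  0.00           N  
ATOM      7  CA ALA A   2      -3.092  -0.182  -1.028  1.00  0.00           C  
ATOM      8  C  ALA A   2      -2.059  -0.586   0.019  1.00  0.00           C  
ATOM      9  O  ALA A   2      -1.524   0.258   0.734  1.00  0.00           O  
ATOM     10  CB ALA A   2      -4.499  -0.539  -0.544  1.00  0.00           C  
ATOM     11  N  ALA A   3      -1.785  -1.884   0.101  1.00  0.00           N  
ATOM     12  CA ALA A   3      -0.817  -2.403   1.060  1.00  0.00           C  
ATOM     13  C  ALA A   3       0.553  -1.763   0.862  1.00  0.00           C  
ATOM     14  O  ALA A   3       1.190  -1.330   1.819  1.00  0.00           O  
ATOM     15  CB ALA A   3      -0.709  -3.924   0.937  1.00  0.00           C  
ATOM     16  N  ALA A   4       0.999  -1.707  -0.389  1.00  0.00           N  
ATOM     17  CA ALA A   4       2.293  -1.120  -0.716  1.00  0.00           C  
ATOM     18  C  ALA A   4       2.377   0.328  -0.244  1.00  0.00           C  
ATOM     19  O  ALA A   4       3.361   0.733   0.371  1.00  0.00           O  
ATOM     20  CB ALA A   4       2.547  -1.198  -2.222  1.00  0.00           C  
ATOM     21  N  ALA A   5       1.337   1.101  -0.537  1.00  0.00           N  
ATOM     22  CA ALA A   5       1.291   2.504  -0.144  1.00  0.00           C  
ATOM     23  C  ALA A   5       1.434   2.659   1.366  1.00  0.00           C  
ATOM     24  O  ALA A   5       2.209   3.484   1.844  1.00  0.00           O  
ATOM     25  CB ALA A   5      -0.014   3.147  -0.618  1.00  0.00           C  
ATOM     26  N  ALA A   6       0.679   1.858   2.112  1.00  0.00           N  
ATOM     27  CA ALA A   6       0.720   1.904   3.568  1.00  0.00           C  
ATOM     28  C  ALA A   6       2.130   1.649   4.089  1.00  0.00           C  
ATOM     29  O  ALA A   6       2.623   2.373   4.952  1.00  0.00           O  
ATOM     30  CB ALA A   6      -0.252   0.882   4.160  1.00  0.00           C  
END
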