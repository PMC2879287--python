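REMARK   idealized base templates, canonical glycosidic frame
REMARK   C1' at origin, glycosidic N on +x, base plane z=0
ATOM      1 C1'  DA T   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2 N9   DA T   1       1.480   0.000   0.000  1.00  0.00           N
ATOM      3 C4   DA T   1       2.291   1.116   0.000  1.00  0.00           C
ATOM      4 C5   DA T   1       3.604   0.690   0.000  1.00  0.00           C
ATOM      5 N7   DA T   1       3.604  -0.690   0.000  1.00  0.00           N
ATOM      6 C8   DA T   1       2.291  -1.116   0.000  1.00  0.00           C
ATOM      7 N3   DA T   1       2.004   2.466   0.000  1.00  0.00           N
ATOM      8 C2   DA T   1       3.030   3.390   0.000  1.00  0.00           C
ATOM      9 N1   DA T   1       4.342   2.963   0.000  1.00  0.00           N
ATOM     10 C6   DA T   1       4.629   1.613   0.000  1.00  0.00           C
ATOM     11 N6   DA T   1       5.913   1.196   0.000  1.00  0.00           N
TER
ATOM     12 C1'  DC T   2       0.000   0.000   0.000  1.00  0.00           C
ATOM     13 N1   DC T   2       1.480   0.000   0.000  1.00  0.00           N
ATOM     14 C2   DC T   2       2.175   1.204   0.000  1.00  0.00           C
ATOM     15 N3   DC T   2       3.565   1.204   0.000  1.00  0.00           N
ATOM     16 C4   DC T   2       4.260   0.000   0.000  1.00  0.00           C
ATOM     17 C5   DC T   2       3.565  -1.204   0.000  1.00  0.00           C
ATOM     18 C6   DC T   2       2.175  -1.204   0.000  1.00  0.00           C
ATOM     19 O2   DC T   2       1.500   2.373   0.000  1.00  0.00           O
ATOM     20 N4   DC T   2       5.610   0.000   0.000  1.00  0.00           N
TER
ATOM     21 C1'  DG T   3       0.000   0.000   0.000  1.00  0.00           C
ATOM     22 N9   DG T   3       1.480   0.000   0.000  1.00  0.00           N
ATOM     23 C4   DG T   3       2.291   1.116   0.000  1.00  0.00           C
ATOM     24 C5   DG T   3       3.604   0.690   0.000  1.00  0.00           C
ATOM     25 N7   DG T   3       3.604  -0.690   0.000  1.00  0.00           N
ATOM     26 C8   DG T   3       2.291  -1.116   0.000  1.00  0.00           C
ATOM     27 N3   DG T   3       2.004   2.466   0.000  1.00  0.00           N
ATOM     28 C2   DG T   3       3.030   3.390   0.000  1.00  0.00           C
ATOM     29 N1   DG T   3       4.342   2.963   0.000  1.00  0.00           N
ATOM     30 C6   DG T   3       4.629   1.613   0.000  1.00  0.00           C
ATOM     31 O6   DG T   3       5.913   1.196   0.000  1.00  0.00           O
ATOM     32 N2   DG T   3       2.749   4.710   0.000  1.00  0.00           N
TER
ATOM     33 C1'  DT T   4       0.000   0.000   0.000  1.00  0.00           C
ATOM     34 N1   DT T   4       1.480   0.000   0.000  1.00  0.00           N
ATOM     35 C2   DT T   4       2.175   1.204   0.000  1.00  0.00           C
ATOM     36 N3   DT T   4       3.565   1.204   0.000  1.00  0.00           N
ATOM     37 C4   DT T   4       4.260   0.000   0.000  1.00  0.00           C
ATOM     38 C5   DT T   4       3.565  -1.204   0.000  1.00  0.00           C
ATOM     39 C6   DT T   4       2.175  -1.204   0.000  1.00  0.00           C
ATOM     40 O2   DT T   4       1.500   2.373   0.000  1.00  0.00           O
ATOM     41 O4   DT T   4       5.610   0.000   0.000  1.00  0.00           O
ATOM     42 C7   DT T   4       4.315  -2.503   0.000  1.00  0.00           C
TER
END
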