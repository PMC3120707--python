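# BLOSUM80 substitution matrix
   A  R  N  D  C  Q  E  G  H  I  L  K  M  F  P  S  T  W  Y  V  B  Z  X  *
A   7  -3  -3  -3  -1  -2  -2   0  -3  -3  -3  -1  -2  -4  -1   2   0  -5  -4  -1  -3  -2  -1  -8
R  -3   9  -1  -3  -6   1  -1  -4   0  -5  -4   3  -3  -5  -3  -2  -2  -5  -4  -4  -2   0  -2  -8
N  -3  -1   9   2  -5   0  -1  -1   1  -6  -6   0  -4  -6  -4   1   0  -7  -4  -5   5  -1  -2  -8
D  -3  -3   2  10  -7  -1   2  -3  -2  -7  -7  -2  -6  -6  -3  -1  -2  -8  -6  -6   6   1  -3  -8
C  -1  -6  -5  -7  13  -5  -7  -6  -7  -2  -3  -6  -3  -4  -6  -2  -2  -5  -5  -2  -6  -7  -4  -8
Q  -2   1   0  -1  -5   9   3  -4   1  -5  -4   2  -1  -5  -3  -1  -1  -4  -3  -4  -1   5  -2  -8
E  -2  -1  -1   2  -7   3   8  -4   0  -6  -6   1  -4  -6  -2  -1  -2  -6  -5  -4   1   6  -2  -8
G   0  -4  -1  -3  -6  -4  -4   9  -4  -7  -7  -3  -5  -6  -5  -1  -3  -6  -6  -6  -2  -4  -3  -8
H  -3   0   1  -2  -7   1   0  -4  12  -6  -5  -1  -4  -2  -4  -2  -3  -4   3  -5  -1   0  -2  -8
I  -3  -5  -6  -7  -2  -5  -6  -7  -6   7   2  -5   2  -1  -5  -4  -2  -5  -3   4  -6  -6  -2  -8
L  -3  -4  -6  -7  -3  -4  -6  -7  -5   2   6  -4   3   0  -5  -4  -3  -4  -2   1  -7  -5  -2  -8
K  -1   3   0  -2  -6   2   1  -3  -1  -5  -4   8  -3  -5  -2  -1  -1  -6  -4  -4  -1   1  -2  -8
M  -2  -3  -4  -6  -3  -1  -4  -5  -4   2   3  -3   9   0  -4  -3  -1  -3  -3   1  -5  -3  -2  -8
F  -4  -5  -6  -6  -4  -5  -6  -6  -2  -1   0  -5   0  10  -6  -4  -4   0   4  -2  -6  -6  -3  -8
P  -1  -3  -4  -3  -6  -3  -2  -5  -4  -5  -5  -2  -4  -6  12  -2  -3  -7  -6  -4  -4  -2  -3  -8
S   2  -2   1  -1  -2  -1  -1  -1  -2  -4  -4  -1  -3  -4  -2   7   2  -6  -3  -3   0  -1  -1  -8
T   0  -2   0  -2  -2  -1  -2  -3  -3  -2  -3  -1  -1  -4  -3   2   8  -5  -3   0  -1  -2  -1  -8
W  -5  -5  -7  -8  -5  -4  -6  -6  -4  -5  -4  -6  -3   0  -7  -6  -5  16   3  -5  -8  -5  -5  -8
Y  -4  -4  -4  -6  -5  -3  -5  -6   3  -3  -2  -4  -3   4  -6  -3  -3   3  11  -3  -5  -4  -3  -8
V  -1  -4  -5  -6  -2  -4  -4  -6  -5   4   1  -4   1  -2  -4  -3   0  -5  -3   7  -6  -4  -2  -8
B  -3  -2   5   6  -6  -1   1  -2  -1  -6  -7  -1  -5  -6  -4   0  -1  -8  -5  -6   6   0  -3  -8
Z  -2   0  -1   1  -7   5   6  -4   0  -6  -5   1  -3  -6  -2  -1  -2  -5  -4  -4   0   6  -1  -8
X  -1  -2  -2  -3  -4  -2  -2  -3  -2  -2  -2  -2  -2  -3  -3  -1  -1  -5  -3  -2  -3  -1  -2  -8
*  -8  -8  -8  -8  -8  -8  -8  -8  -8  -8  -8  -8  -8  -8  -8  -8  -8  -8  -8  -8  -8  -8  -8   1
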