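phoneme,voiced,continuant,sonorant,low,tense,back,strident,consonantal,long,syllabic,round,high,coronal,anterior,nasal,labial,lateral
p,0,0,0,0,0,0,0,1,0,0,0,0,0,1,0,1,0
b,1,0,0,0,0,0,0,1,0,0,0,0,0,1,0,1,0
t,0,0,0,0,0,0,0,1,0,0,0,0,1,1,0,0,0
d,1,0,0,0,0,0,0,1,0,0,0,0,1,1,0,0,0
k,0,0,0,0,0,1,0,1,0,0,0,1,0,0,0,0,0
g,1,0,0,0,0,1,0,1,0,0,0,1,0,0,0,0,0
pf,0,0,0,0,0,0,1,1,0,0,0,0,0,1,0,1,0
ts,0,0,0,0,0,0,1,1,0,0,0,0,1,1,0,0,0
tS,0,0,0,0,0,0,1,1,0,0,0,1,1,0,0,0,0
dZ,1,0,0,0,0,0,1,1,0,0,0,1,1,0,0,0,0
f,0,1,0,0,0,0,1,1,0,0,0,0,0,1,0,1,0
v,1,1,0,0,0,0,1,1,0,0,0,0,0,1,0,1,0
s,0,1,0,0,0,0,1,1,0,0,0,0,1,1,0,0,0
z,1,1,0,0,0,0,1,1,0,0,0,0,1,1,0,0,0
S,0,1,0,0,0,0,1,1,0,0,0,1,1,0,0,0,0
Z,1,1,0,0,0,0,1,1,0,0,0,1,1,0,0,0,0
C,0,1,0,0,0,0,0,1,0,0,0,1,0,0,0,0,0
x,0,1,0,0,0,1,0,1,0,0,0,1,0,0,0,0,0
h,0,1,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0
m,1,0,1,0,0,0,0,1,0,0,0,0,0,1,1,1,0
n,1,0,1,0,0,0,0,1,0,0,0,0,1,1,1,0,0
N,1,0,1,0,0,1,0,1,0,0,0,1,0,0,1,0,0
l,1,1,1,0,0,0,0,1,0,0,0,0,1,1,0,0,1
R,1,1,1,0,0,1,0,1,0,0,0,0,0,0,0,0,0
j,1,1,1,0,0,0,0,0,0,0,0,1,0,0,0,0,0
i:,1,1,1,0,1,0,0,0,1,1,0,1,0,0,0,0,0
I,1,1,1,0,0,0,0,0,0,1,0,1,0,0,0,0,0
y:,1,1,1,0,1,0,0,0,1,1,1,1,0,0,0,0,0
Y,1,1,1,0,0,0,0,0,0,1,1,1,0,0,0,0,0
e:,1,1,1,0,1,0,0,0,1,1,0,0,0,0,0,0,0
E,1,1,1,0,0,0,0,0,0,1,0,0,0,0,0,0,0
E:,1,1,1,0,0,0,0,0,1,1,0,0,0,0,0,0,0
2:,1,1,1,0,1,0,0,0,1,1,1,0,0,0,0,0,0
9,1,1,1,0,0,0,0,0,0,1,1,0,0,0,0,0,0
a,1,1,1,1,0,0,0,0,0,1,0,0,0,0,0,0,0
a:,1,1,1,1,1,0,0,0,1,1,0,0,0,0,0,0,0
o:,1,1,1,0,1,1,0,0,1,1,1,0,0,0,0,0,0
O,1,1,1,0,0,1,0,0,0,1,1,0,0,0,0,0,0
u:,1,1,1,0,1,1,0,0,1,1,1,1,0,0,0,0,0
U,1,1,1,0,0,1,0,0,0,1,1,1,0,0,0,0,0
@,1,1,1,0,0,0,0,0,0,1,0,0,0,0,0,0,0
6,1,1,1,1,0,0,0,0,0,1,0,0,0,0,0,0,0
aI,1,1,1,1,1,0,0,0,1,1,0,0,0,0,0,0,0
aU,1,1,1,1,1,1,0,0,1,1,1,0,0,0,0,0,0
OY,1,1,1,0,1,1,0,0,1,1,1,0,0,0,0,0,0
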