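je
tu
il
elle
on
nous
vous
ils
elles
le
la
les
un
une
des
du
de
d
l
et
ou
mais
donc
ne
pas
que
qui
quoi
dont
a
au
aux
ce
cette
ces
mon
ma
mes
ton
ta
tes
son
sa
ses
pour
par
avec
sans
dans
sur
sous
est
suis
es
sont
ai
as
avons
avez
ont
en
y
se
me
te
moi
toi
lui
leur
tres
plus
moins
si
comme
hier
matin
depuis
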