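consonant	ipa	voice	manner	place
b	b	voiced	plosive	front
ch	tʃ	voiceless	plosive	back
d	d	voiced	plosive	middle
f	f	voiceless	fricative	front
g	ɡ	voiced	plosive	back
jh	dʒ	voiced	plosive	back
k	k	voiceless	plosive	back
l	l	voiced	approximant	middle
m	m	voiced	nasal	front
n	n	voiced	nasal	middle
p	p	voiceless	plosive	front
r	r	voiced	approximant	middle
s	s	voiceless	fricative	middle
sh	ʃ	voiceless	fricative	back
t	t	voiceless	plosive	middle
th	θ	voiceless	fricative	middle
v	v	voiced	fricative	front
w	w	voiced	approximant	front
y	j	voiced	approximant	back
z	z	voiced	fricative	middle
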