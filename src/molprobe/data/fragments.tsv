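naphthalene	c1ccc2ccccc2c1
anthracene	c1ccc2cc3ccccc3cc2c1
tetracene	c1ccc2cc3cc4ccccc4cc3cc2c1
pyrene	c1cc2ccc3cccc4ccc(c1)c2c34
perylene	c1cc2c3c(c1)ccc1ccc4cccc-2c4c13
p-benzoquinone	O=C1C=CC(=O)C=C1
1,4-naphthoquinone	O=C1C=CC(=O)c2ccccc21
9,10-anthraquinone	O=C1c2ccccc2C(=O)c2ccccc21
1,8-naphthalimide	O=C1NC(=O)c2cccc3cccc1c23
naphthalene-diimide	O=C1NC(=O)c2ccc3c4c2c1ccc4C(=O)NC3=O
perylene-diimide	O=C1NC(=O)c2ccc3c4ccc5c6c(ccc(c7ccc1c2c73)c64)C(=O)NC5=O
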