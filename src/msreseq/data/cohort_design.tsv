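sample_id	diagnosis	age	sex	gmfcs	tissue_source
CN1	Spondylolysis	16.6	M	NA	Spinalis
CN2	Torn ACL	12.6	M	NA	Semitendinosus
CN3	Idiopathic scoliosis	12.1	F	NA	Spinalis
CN4	Torn ACL	12.7	F	NA	Semitendinosus
CN5	Idiopathic scoliosis	15.1	M	NA	Spinalis
CN6	Idiopathic scoliosis	14.3	F	NA	Spinalis
CP1	Spastic CP	15.6	M	5	Vastus lateralis
CP2	Spastic CP	19.1	M	5	Adductor longus
CP3	Spastic CP	12.6	M	4	Rectus femoris
CP4	Spastic CP	13.8	F	2	Rectus femoris
CP5	Spastic CP	19.0	F	5	Spinalis
CP6	Spastic CP	12.8	F	5	Spinalis
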