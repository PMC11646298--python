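name	kind	strand	start	end
trnF	tRNA	+	1	68
rrnS	rRNA	+	69	1018
trnV	tRNA	+	1019	1090
rrnL	rRNA	+	1091	2757
trnL2	tRNA	+	2758	2831
nad1	PCG	+	2832	3806
trnI	tRNA	+	3807	3876
trnQ	tRNA	-	3877	3947
trnM	tRNA	+	3948	4016
nad2	PCG	+	4017	5061
trnW	tRNA	+	5062	5132
trnA	tRNA	-	5133	5201
trnN	tRNA	-	5202	5274
trnC	tRNA	-	5275	5340
trnY	tRNA	-	5341	5407
cox1	PCG	+	5408	6958
trnS2	tRNA	-	6959	7029
trnD	tRNA	+	7030	7101
cox2	PCG	+	7102	7792
trnK	tRNA	+	7793	7866
atp8	PCG	+	7867	8034
atp6	PCG	+	8035	8717
cox3	PCG	+	8718	9502
trnG	tRNA	+	9503	9573
nad3	PCG	+	9574	9922
trnR	tRNA	+	9923	9991
nad4l	PCG	+	9992	10288
nad4	PCG	+	10289	11669
trnH	tRNA	+	11670	11738
trnS1	tRNA	+	11739	11805
trnL1	tRNA	+	11806	11877
nad5	PCG	+	11878	13716
nad6	PCG	-	13717	14238
trnE	tRNA	-	14239	14307
cytb	PCG	+	14308	15448
trnT	tRNA	+	15449	15520
trnP	tRNA	-	15521	15590
CR	CR	+	15591	16421
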