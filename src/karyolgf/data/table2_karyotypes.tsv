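# Karyotypes of the 37 OSU tetraploid/near-tetraploid MDS/AML cases (short-form ISCN,
# transcribed verbatim including ".ish" annotations, "inc", and in-bracket annotations).
# complexity_printed is the published per-case complexity call: C complex, N non-complex,
# Inc not evaluable (incomplete karyotype). It is an expected output used by tests, not an input.
case_id	complexity_printed	karyotype	cohort
1	C	44~49,XY,-2,-5,del(7)(q22),-19,+21,add(21)(p11.2)x2,+2-5mar[cp9]/47~49,sl,add(12)(q24.3)[cp3]/87~113,slx2[cp4]/46,XY[3]	OSU
2	C	86~92<4n>,XXYY,del(2)(p23p25)x2,-5,-5,-9,-9,add(11)(p15)x2,-13,-17,-17,+22,+mar1x2,+mar2x2,+mar3x2,dmin[cp19]/46,XY[1].ish dmin(CMYC+)	OSU
3	C	72~98<4n>,XYY,-X,+1,i(1)(q10),+8,+8,-11,+12,+12,+16[4,three w/nonclonal abnormalities]/46,XY[16,one is 4n]/nonclonal[1]	OSU
4	C	46,XX,del(5)(q13q33),del(20)(q11.2q13.1)[2]/77~89,idemx2,del(1)(q21),-2,-3,del(3)(p25),+8,add(10)(q24),hsr(11)(q23),hsr(11)(q23),-11,add(13)(q34),-16,-17,-17,-17,del(18)(q21),+19,+19,add(19)(p13),der(19)t(17;19)(q21;p13)x2,+20,+20,-del(20),-del(20),+mar[cp18]/46,XX[4]/nonclonal[1].ish hsr(11)(amp MLL),hsr(11)(amp MLL)	OSU
5	C	83~88<4n>,XXYY,i(1)(q10),-2,-3,-7,-9,-17,i(17)(q10),+18[cp18]/46,XY[2]/4n[1]	OSU
6	C	85~90<4n>,XXXX,-8,-9,-9,-12,-17,i(17)(q10),+mar1x2,+mar2,+dmin[cp10]/81~89,idem,-2,-5,-5,-7[cp7]/46,XX[6]	OSU
7	C	45~50,XY,-5,der(7)t(5;7)(p14;p12)add(7)(q11.2),der(13;14)(q10;q10)c,+21,+mar1,+mar2,+mar3,+mar4,+mar5[cp8]/44,sl,add(4)(p16),add(12)(p12),add(19)(p13),-mar1,-mar4,-mar5[cp3]/85~87,slx2,+1,add(19)(p13)x2,-mar1,-mar1,-mar2,-mar3,-mar4,-mar5,+mar6[cp4]/45,XY,der(13;14)(q10;q10)c[1].ish der(7)t(5;7)(D5S23:D5S721+,D7Z1+,D7S486-)	OSU
8	C	46,XY,t(9;22)(q34;q11.2)[11]/89-93,idemx2,+4,add(4)(q31)x2[7]/nonclonal Ph+[2]	OSU
9	N	94<4n>,XXYY,+13,+13[cp15]/46,XY[3]/nonclonal[2]	OSU
10	N	46,XY,del(6)(p23)[17]/90-92,sl,x2[2]/46,sl,add(19)(p13.3)[1]	OSU
11	C	90<4n>,XXYY,add(2)(q31),-7,-7[4]/90,sl,del(5)(q31q35)[cp14]/46,XY[2]	OSU
12	C	97,XXYY<4n>,+1,t(1;8)(q32;q24),der(1)t(1;8),-3,+4,del(5)(q31q35),del(7)(q10),+10,+12,add(12)(q13)x3,+21,+22[17]/nonclonal w/clonal abnormalities[3]	OSU
13	C	47,XX,+10[2]/94-99<4n>,XXXX,+X,+X(4),-2,-7(6),-9,+10,+10,+10,-16,+20(9),+der(?)t(?;1)(?;q25)x2,+mar1[cp18]	OSU
14	C	90<4n>,XX,-Y,-Y,del(5)(q14)[15]/93,idem,+8,+11,+13[5]	OSU
15	C	90<4n>,XX,-Y,-Y,add(7)(q36)x2[cp5]/46,XY[13]/nonclonal[2]	OSU
16	C	45~47,XX,del(3)(p13),del(5)(q11.2q35),add(17)(p13),-20,+mar1[cp5]/48,idem,-del(3)(p13),+add(20)(q11.2),+22,+mar2[cp8]/76~97,idemx2,-del(3)(p13)x2,-5,+add(20)(q11.2)x2,+22,+mar2x2[cp4]/120~134,idemx3[cp2]/46,XX[1]	OSU
17	N	92<4n>,XXYY,der(5)t(1;5)(q21;q31)[18]/46,XY[2]	OSU
18	C	71~83<4n>,XXYY,add(2)(q37),del(2)(q33q35),-7,-13,-13,-13,add(13)(p12),-14,add(14)(p13),-15,-16,-17,-18,-20,+21,idic(21)(p13),psu dic(21;13)(p11.2;p13),-22,+mar1,+mar2,+mar3,+mar4,+mar5[cp5]/74~83,idem,-add(13)[cp14]/46,XY[1]	OSU
19	C	46~48,X,-Y,dup(1)(q23q42),del(5)(q13q33),-7,del(7)(q11.2),+8,der(11)t(Y;11)(q11.2;p13),+20,add(20)(q11.2)x2,+mar1[cp3]/42,sl,add(3)(p25),-8,-12,-17,-add(20),-mar1[7]/42,sl,+1,-dup(1),-3,+7,-del(7),-8,del(12)(p11.2p13),-16,-mar1,+mar2[cp7]/88-90,sdl2x2,+mar3[cp3]	OSU
20	C	46,XY,-1,-5,+8,+11,add(11)(p11.2)x2,-17,der(17)t(1;17)(p22;p11.2),+mar[12]/77~79,idemx2,-2,-3,-8,-8,-add(11),-add(11),-12,-14,-16,-mar[cp5]/46,XY[3]	OSU
21	C	73~87<4n>,XXXX,-7,-7,t(8;21)(q22;q22)x2,-11,-14,-16,-20[cp20]	OSU
22	C	44,X,-Y,add(5)(q11.2),-9,-12,der(17;18)(q10;q10),+mar1,+mar2[2]/85,idemx2,-2,-3,-7[17]/nonclonal[1]	OSU
23	C	99~110<4n>,XXYY,+2,+3,+8,+10,+12,+13,+13,+13,+16,+18,+19,+20,+21,+22,+22,+mar1x2[cp8]/81~82<3n>,XY,-X,+Y,+2,+9,+10,+13,+13,+14,+14,+15,+15,+19,+20,+21,+22[cp3]/46,XY[9]	OSU
24	C	82~88<4n>XXXX,-1,t(3;11)(p13;q21),-5,del(5)(q13q31),dic(9;21)(q12;p13),-13,-13,-16,-17,-17,dic(17;21)(p13;p12),-18,-18,-18,+21,add(22)(p13),+der(?)t(?;1)(?;p13),+der(?)t(?;1)(?:q21),+mar1,+mar2[cp8]/82-88,sl,-der(11)t(3;11)[cp16].ish t(3;11)(MLL+,MLL-)	OSU
25	N	94<4n>,XXXX,+13,+13[cp3]/46,XX[19]/4n[1]	OSU
26	C	92~95<4n>,XXXX,+2,+2,del(2)(q33q37)x3,+13,+13,-21[6]/90~95,sl,+2,del(2)[3]/90-95,sdl1,-21[5]/86~94,sl,-21[3]/46,XX,t(1;12)(p36.1;p13)[2]/46,XX[1]	OSU
27	N	92<4n>,XXYY[7]/46,XY[13]	OSU
28	C	45,X,-Y,del(5)(q13q33),add(14)(q24),-17,-19,+mar1,+mar2[cp9]/90,slx2,add(11)(p15)x2[cp10]/46,XY[4]	OSU
29	C	46,XX,add(7)(q36),-10,+mar[17]/92,slx2[2]/46,XX[1]	OSU
30	C	46,XX,del(5)(q13q35),add(7)(q11.2),-11,add(17)(p11.2),+20,del(20)(q11.2q13.3),dic(20;22)(q11.2;p11.2),+der(?)t(?;11)(?;q12),dmin[6,two w/nonclonal abnormalities]/45,sl,der(16)t(1;16)(p13;p11.2),-del(20)[6,two w/nonclonal abnormalities]/89,sdl1x2,+16,-der(16)t(1;16)x2[2]/90,sdl2,+1[2]/47,sl,+ider(?)(11qter->11q12::?::11q12->11qter)[2,one is 4n]/46,XX[2]	OSU
31	C	43,X,-Y,del(5)(q22q35),add(7)(q21),+8,add(9)(q13),-10,add(11)(p15),der(12)del(12)(p12p13)add(12)(q13),+15,add(15)(q22),-16,-17,-18,-19,add(20)(p12),+mar1[2,one w/nonclonal abnormalities]/82~85,slx2,idic(1)(q44),-del(7)x2,+17,+18[cp4]/75,sdl1,+1,+add(1)(q21),-dic(1;1)[cp3]/72~79,sdl2,+add(1)(q25),-add(1)(q21),-15[cp4]/69~75,sdl1,-15,-15,-21,-mar1[cp3]/46,XY[4]	OSU
32	C	43~51,XY,+1,+2,-3,-5,+6,-7,+8,del(9)(q13q22),add(12)(p13),+13,+14,+15,+15,-17,add(17)(p11.2),+18,der(20)(20pter->20q13.1::?::5p15.2->5p15.2::?),+21,+21,der(21)add(21)(p13)del(21)(q22),der(21)t(9;21)(q13;p13)x2,+22,+mar[cp4]/42~55,sl,add(3)(p13),+9,del(9)(q13q22),+11,-14,-22[cp5]/84,sdl1x2,-X,-1,-1,-2,-2,-del(3),add(4)(q21),-8,-9,-del(9),-10,-13,-13,-13,-add(17),-19,-der(21)add(21)del(21)[cp3]/51~81,sl,der(1)t(1;9)(p13;q13),-2,+8,del(9)(q13q22),-15,+19,+21,+der(21)add(21)del(21),+der(21)t(9;21)[cp4,2 are 4n]/82~84,slx2,-X,-2,-2,-4,+8,-12,-13,-22,-22[cp2]/46,XY[2].ish add(12)(ETV6-),der(20)(D5S23:D5S721+,D20S108+),der(21)t(9;21)(RUNX1+)	OSU
33	Inc	91<4n>,XXXX,-17,inc[cp5]/46,XX[15]/nonclonal[3]	OSU
34	Inc	88~91<4n>,XXYY,inc[cp5]/46,XY[18]	OSU
35	C	47,XX,+10[1]/85,slx2,-5,-6,-7,-8,-10,-15,-16,-17,-18[7]/85,sdl1,-2,+r[5]/46,sl,dic(7;16)(p13;q12.1)[5]/46,XX[2]	OSU
36	N	90<4n>,XXXX,inv(3)(q21.3q26.2)x2[1]//46,XY[19]/nonclonal[1]	OSU
37	C	45,XX,der(5)t(5;16)(q13;q22),del(13)(q12q22),-16,add(17)(p13),der(17)del(17)(q11.2)del(17)(q11.2),add(22)(q13),+psu dic(?;17)(?::17q21->17q21::17p11.2->17q11.2::17q21->17q21::?)[18,one w/nonclonal abnormalities]/92,slx2[cp2].ish der(2)cryp ins(2;17)(TP53+),der(5)t(5;16)(CBFB+),add(17)(TP53+),psu dic(?;17)(TP53-,RARA+,D17Z1+,RARA+)	OSU
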