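patient,chronic_karyotype,blast_karyotype
CML 01,"46,XY,t(9;22)(q34;q11.2)[20]","46–47,XY,+ 8[5],t(9;22)(q34;q11.2)[20]"
CML 02,"46,XX,t(9;22)(q34;q11.2)[20]","46–48,XX,+ 8[7],+ 19[2],t(9;22)(q34;q11.2)[20]"
CML 03,"46,XX,t(9;22)(q34;q11.2)[20]","46–47,XX,+ 8[12],t(9;22)(q34;q11.2)[16]"
CML 04,"46,XX,t(9;22)(q34;q11.2)[20]","46,XX,t(9;22)(q34;q11.2)[14],del(13)(q14q32)[7]"
CML 05,"46,XY,t(9;22)(q34;q11.2)[20]","47,XY,+i(9)(q10),t(9;22)(q34;q11.2)(q34;q11.2)[16]"
CML 06,"46,XY,t(9;22)(q34;q11.2)[20]","44,XY,der(5;17)(q10;q10),-7,add(20)(q13)[16]"
CML 07,"46,XY,t(9;22)(q34;q11.2)[20]","47,XY,+ 8,t(9;11)(p21–22;q23)"
CML 08,"46,XY,t(9;22)(q34;q11.2)[20]","47,XY,del(6)(q23q25),+ 7[20]"
CML 09,"46,XY,t(9;22)(q34;q11.2)[28]","46,XY,del(7)(q22;qter),t(9;22)(q34;q11.2)[13]/46,XY[2]"
CML 10,"46,XX,t(9;22)(q34;q11.2)[22]","46,XX,t(9;22)(q34;q11.2),del(20)(p11)[17]/46,XX,del(20)(p11)[3]"
CML 11,"46,XY,t(9;22)(q34;q11.2)[22]","46,XY,t(9;22)(q34;q11.2)[5]/46,XY,t(11;22;X)(q13;q11.2;p22.3)[20]"
CML 12,"46,XX,t(9;22)(q34;q11.2)[20]/46,XX[10]","46,XX,t(9,22)(q34;q11.2)[1]/47,XX,+ 8[2]/46,XX[17]"
CML 13,"46,XY,t(9;22)(q34;q11.2)[28]","46,XY,t(9,22)(q34;q11.2)[5]/47,XY,+ 8[21]"
CML 14,"46,XY,t(9;22)(q34;q11.2)[22]","47,XY,+ 8,t(9;22)(q34;q11.2),iso(17q)[20]"
CML 15,"46,XX,t(9;22)(q34;q11.2)[30]","46,XX,t(9,22)(q34;q11.2)[4]/48,XX,+ 8,t(9;22)(q34;q12),+ 19[20]"
CML 16,"46,XX,t(9;22)(q34;q11.2)[21]","46,XX,t(9,22)(q34;q11.2)[5]/48,XX,+ 8,t(9;22)(q34;q11.2),iso(17q),+ 21[18]"
CML 17,"46,XY,t(9;22)(q34;q11.2)[23]","45,XY,-7,t(9;22)(q34;q11.2)[20]"
CML 18,"46,XY,t(9;22)(q34;q11.2)[27]","48,XY,+ 8,t(9;22)(q34;q12),+ 19[20]"
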