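group_number,group_name,icd_ranges
1,Acute respiratory,H65-H68;H70-H71;J00-J22;J32;J36;J85-J86;P23
2,HIV/AIDS,B20-B24
3,Diarrhoeal,A00-A09
4,Pulmonary TB,A15-A16;B90;J65
5,Other and unspecified infections,A17-A33;A35-A99;B00-B17;B19;B25-B89;B91-B99;C46;D64;D84;G00-G09;H10;H60;I30;I32-I33;K02;K04-K05;K61;K65;K67;K81;L00-L04;L08;M00-M01;M60;M86;N10;N30;N34;N41;N49;N61;N70-N74;P35-P39;R50;R75;ZZ21
6,Neoplasms,C00-C26;C30-C45;C47-C58;C60-C97;D00-D48;D91;N60;N62-N64;N87;R59
7,Nutrition and endocrine,D50-D53;E00-E02;E40-E46;E50-E64;X53-X54
8,Cardiovascular,E10-E14;G45-G46;G81-G83;I60-I69;I00-I03;I05-I15;I26-I28;I31;I34-I52;I70-I99;R00-R01;R03;ZZ23
9,Chronic respiratory,J30-J31;J33-J35;J37-J64;J66-J84;J90-J99;R04-R06;R84;R91
10,Liver cirrhosis,B18;F10;K70-K77;R16-R18;X45;Y15;Y90-Y91
11,Other non-communicable diseases,D55-D63;D65-D83;D86;D89;E03-E07;E15-E35;E65-E68;E70-E90;F00-F09;F11-F52;F54-F99;G10-G37;G40-G41;G50-G80;G84-G99;H00-H06;H11-H59;H61-H62;H69;H72-H95;K00-K01;K03;K06-K14;K20-K31;K35-K38;K40-K60;K62-K64;K66;K78-K80;K82-K93;L05;L10-L99;M02-M54;M61-M85;M87-M99;N00-N08;N11-N29;N31-N33;N35-N40;N42-N48;N50-N59;N75-N86;N88-N99;Q00-Q99;R10-R15;R19-R23;R26-R27;R29-R49;R56;R63;R70-R74;R76-R77;R80-R82;R85-R87;R90;ZZ25
12,Neonatal,C76;D64;G40;O60;P00;P01;P02-P03;P05;P07;P10-P15;P21;P22;P24-P29;P50-P52;P61;P77;P80;P90-P92;R04;R06;Q00-Q99;W79;Z37
13,Road and transport injuries,V01-V99;Y85
14,Other injuries,S00-S99;T00-T99;W00-W99;X00-X44;X46-X52;X55-X59;X85-X99;Y00-Y14;Y16-Y84;Y86-Y89;Y92-Y98;ZZ27
15,Ill-defined,P96;R02;R07-R09;R25;R51-R54;R57-R58;R60-R62;R64-R69;R78-R79;R83;R89;R92-R94;R96;R98-R99
16,Suicide,X60-X84
17,Maternal,A34;F53;O00-O08;O10-O16;O20-O99
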