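compound,cas,migration,migration_unc,sml,cramer_class,tdi,edi
Irgafos 168,31570-04-4,2.0,0.2,-,,,
Methyl palmitate,112-39-0,0.058,,,I,1.80,0.058
Methyl stearate,112-61-8,0.058,,,I,1.80,0.058
"1,2-Diphenoxyethane",104-66-5,0.033,,,III,0.09,0.033
Octadecane,593-45-3,0.021,,,I,1.80,0.021
Bis(2-ethylhexyl) terephthalate,6422-86-2,0.020,0.002,60,,,
Tetracosane,646-31-1,0.018,,,I,1.80,0.018
Octacosane,630-02-4,0.013,,,I,1.80,0.013
Butylated hydroxytoluene,128-37-0,0.010,0.001,3,,,
Hexadecane,544-76-3,0.009,,,I,1.80,0.009
Methyl dehydroabietate,1235-74-1,0.009,,,I,1.80,0.009
Tetraiacontane,14167-59-0,0.007,,,I,1.80,0.007
Eicosane,112-95-8,0.005,,,I,1.80,0.005
Benzophenone,119-61-9,0.0030,0.0005,0.6,,,
Bis(2-ethylhexyl) phthalate,117-81-7,0.0025,0.0005,1.5,,,
"2,6-Di-tert-butylphenol",128-39-2,0.002,,,II,0.54,0.002
"N,N-Dimethylpalmitylamine",112-69-6,0.002,,,I,1.80,0.002
Octadecyl trifluoroacetate,79392-43-1,0.0014,,,III,0.09,0.0014
"2,6-Diisopropylnaphthalene",24157-81-1,0.0014,,,III,0.09,0.0014
Diisobutyl phthalate,84-69-5,0.0014,0.0002,,I,1.80,0.0014
Irganox 1076,2082-79-3,0.0013,,6,,,
"7,9-Di-tert-butyl-1-oxaspiro(4,5)deca-6,9-diene-2,8-dione",82304-66-3,0.0010,,,III,0.09,0.0010
Methyl linolelaidate,2566-97-4,0.0009,,,I,1.80,0.0009
1-Tetracosene,10192-32-2,0.0009,,,I,1.80,0.0009
"2,4-Di-tert-pentylphenol",120-95-6,0.0008,,,I,1.80,0.0008
Methyl elaidate,1937-62-8,0.0007,,,I,1.80,0.0007
Nonadecanol,1454-84-8,0.0007,,,I,1.80,0.0007
Squalene,111-02-4,0.0007,,,I,1.80,0.0007
"3,5-Di-tert-butyl-4-hydroxybenzaldehyde",1620-98-0,0.0005,,,II,0.54,0.0005
"2,4-Di-tert-butylphenol",96-76-4,0.0005,,,I,1.80,0.0005
"2,6-Di-tert-butyl-1,4-benzoquinone",719-22-2,0.0005,,,II,0.54,0.0005
Bis(2-ethylhexyl) adipate,103-23-1,0.0005,0.0001,18,,,
Galaxolide,1222-05-5,0.0005,,,III,0.09,0.0005
1-Chlorohexadecane,4860-03-1,0.0004,,,III,0.09,0.0004
1-Hexadecene,629-73-2,0.0003,,,I,1.80,0.0003
Hexadecyl palmitate,540-10-3,0.0003,,,I,1.80,0.0003
Isopropyl myristate,110-27-0,0.0003,,,I,1.80,0.0003
Hexadecyl trifluoroacetate,6222-03-3,0.0003,,,III,0.09,0.0003
Methyl abietate,127-25-3,0.0003,,,III,0.09,0.0003
"2,6,10,15-Tetramethylheptadecane",54833-48-6,0.0003,,,I,1.80,0.0003
Butyl palmitate,111-06-8,0.0002,,-,,,
11-Methyltricosane,27538-41-6,0.0002,,,I,1.80,0.0002
Hexadecyl acetate,629-70-9,0.0002,,,I,1.80,0.0002
3-Nonenol,10340-23-5,0.00018,,,I,1.80,0.00018
Metilox,6386-38-5,0.00017,,,I,1.80,0.00017
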