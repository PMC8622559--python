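category,compound,cas,formula,total_score,delta_ri,ias
Acetate esters,7-Tetradecen-1-yl acetate,16974-10-0,C16 H30 O2,93.2,24,0
Acetate esters,Hexadecyl acetate,629-70-9,C18 H36 O2,93.5,3,0
Acetate esters,Hexadecyl trifluoroacetate,6222-03-3,C18 H33 F3 O2,95.9,20,0
Acetate esters,Octadecyl trifluoroacetate,79392-43-1,C20 H37 F3 O2,95.6,14,0
Acetate esters,Tri-n-butyl acetyl citrate,77-90-7,C20 H34 O8,95.7,4,1
Aldehydes and ketones,Benzophenone,119-61-9,C13 H10 O,95.8,8,1
Aldehydes and ketones,"2,6-Di-tert-butyl-1,4-benzoquinone",719-22-2,C14 H20 O2,94.9,10,0
Aldehydes and ketones,"3,5-Di-tert-butyl-4-hydroxybenzaldehyde",1620-98-0,C15 H22 O2,96.1,17,0
Aldehydes and ketones,"7,9-Di-tert-butyl-1-oxaspiro(4,5)deca-6,9-diene-2,8-dione",82304-66-3,C17 H24 O3,96.1,21,0
Aldehydes and ketones,Dehydroabietic aldehyde,13601-88-2,C20 H28 O,96.4,1,0
Alkenes,1-Hexadecene,629-73-2,C16 H32,96.5,1,0
Alkenes,9-Nonadecene,31035-07-1,C19 H38,91.4,29,0
Alkenes,1-Docosene,1599-67-3,C22 H44,91.3,50,0
Alkenes,9-Tricosene,27519-02-4,C23 H46,93.5,3,0
Alkenes,1-Tetracosene,10192-32-2,C24 H48,95.3,0,0
Alkenes,1-Hexacosene,18835-33-1,C26 H52,93.7,2,0
Alkenes,Squalene,111-02-4,C30 H50,96.4,0,0
Phenol derivatives,"1,2-Diphenoxyethane",104-66-5,C14 H14 O2,97.5,10,0
Phenol derivatives,"2,4-Di-tert-butylphenol",96-76-4,C14 H22 O,97.2,12,0
Phenol derivatives,"2,6-Di-tert-butylphenol",128-39-2,C14 H22 O,96.8,10,0
Phenol derivatives,Butylated hydroxytoluene,128-37-0,C15 H24 O,97.0,9,1
Phenol derivatives,"2,4-Di-tert-pentylphenol",120-95-6,C16 H26 O,92.6,38,0
Phenol derivatives,Metilox,6386-38-5,C18 H28 O3,94.7,16,0
Phenol derivatives,Irganox 1076,2082-79-3,C35 H62 O3,93.0,8,1
Phthalates,Dibutyl phthalate,84-74-2,C16 H22 O4,94.6,2,1
Phthalates,Diisobutyl phthalate,84-69-5,C16 H22 O4,96.4,13,0
Phthalates,Bis(2-ethylhexyl) phthalate,117-81-7,C24 H38 O4,98.2,2,1
Phthalates,Bis(2-ethylhexyl) terephthalate,6422-86-2,C24 H38 O4,94.7,28,1
Primary alcohols,3-Nonenol,10340-23-5,C9 H18 O,95.7,48,0
Primary alcohols,Octadecanol,112-92-5,C18 H38 O,96.2,3,0
Primary alcohols,Nonadecanol,1454-84-8,C19 H40 O,96.3,18,0
Primary alcohols,Eicosanol,629-96-9,C20 H42 O,90.9,20,0
Primary alcohols,Docosanol,661-19-8,C22 H46 O,90.4,12,0
Primary alcohols,Tetracosanol,506-51-4,C24 H50 O,86.2,11,0
Cyclic and aromatic hydrocarbons,"2,6-Diisopropylnaphthalene",24157-81-1,C16 H20,96.7,8,0
Cyclic and aromatic hydrocarbons,"2,2',5,5'-Tetramethyl-1,1'-biphenyl",3075-84-1,C16 H18,94.2,42,0
Cyclic and aromatic hydrocarbons,Undecylcyclohexane,54105-66-7,C17 H34,94.6,3,0
Cyclic and aromatic hydrocarbons,1-Ethyldecylbenzene,2400-00-2,C18 H30,90.3,1,0
Cyclic and aromatic hydrocarbons,"7-Isopropyl-1-methyl-1,2,3,4-tetrahydrophenanthrene",6566-19-4,C18 H22,96.2,11,0
Cyclic and aromatic hydrocarbons,"7-Isopropyl-1,4-dimethyltetradecahydrophenanthrene",2221-95-6,C19 H34,96.7,9,0
Cyclic and aromatic hydrocarbons,m-Camphorene,20016-73-3,C20 H32,92.6,44,0
Cyclic and aromatic hydrocarbons,"1,3,5-Triphenylcyclohexane",28336-57-4,C24 H24,95.3,31,0
Fatty acid methyl esters (FAMEs),Methyl laurate,111-82-0,C13 H26 O2,95.8,13,0
Fatty acid methyl esters (FAMEs),Methyl palmitate,112-39-0,C17 H34 O2,97.7,16,0
Fatty acid methyl esters (FAMEs),Methyl heptadecanoate,1731-92-6,C18 H36 O2,94.2,11,0
Fatty acid methyl esters (FAMEs),Methyl linolelaidate,2566-97-4,C19 H34 O2,98.0,20,0
Fatty acid methyl esters (FAMEs),Methyl elaidate,1937-62-8,C19 H36 O2,98.1,4,0
Fatty acid methyl esters (FAMEs),Methyl stearate,112-61-8,C19 H38 O2,97.8,12,0
Fatty acid methyl esters (FAMEs),Methyl erucate,1120-34-9,C23 H44 O2,91.8,0,0
Fatty acid methyl esters (FAMEs),Methyl isopimarate,1686-62-0,C21 H32 O2,92.1,1,0
Fatty acid methyl esters (FAMEs),Methyl icosanoate,1120-28-1,C21 H42 O2,97.2,13,0
Other fatty acid esters (FAEs),Isopropyl myristate,110-27-0,C17 H34 O2,94.3,4,0
Other fatty acid esters (FAEs),Ethyl palmitate,628-97-7,C18 H36 O2,92.1,1,0
Other fatty acid esters (FAEs),Butyl palmitate,111-06-8,C20 H40 O2,93.1,4,1
Other fatty acid esters (FAEs),Butyl stearate,123-95-5,C22 H44 O2,94.3,3,1
Other fatty acid esters (FAEs),Hexadecyl palmitate,540-10-3,C32 H64 O2,95.0,0,0
Linear and branched polyethylene oligomers,Tetradecane,629-59-4,C14 H30,96.5,0,0
Linear and branched polyethylene oligomers,Hexadecane,544-76-3,C16 H34,96.7,0,0
Linear and branched polyethylene oligomers,Heptadecane,629-78-7,C17 H36,96.9,2,0
Linear and branched polyethylene oligomers,Octadecane,593-45-3,C18 H38,96.6,0,0
Linear and branched polyethylene oligomers,Eicosane,112-95-8,C20 H42,96.5,0,0
Linear and branched polyethylene oligomers,Tetracosane,646-31-1,C24 H50,95.7,0,0
Linear and branched polyethylene oligomers,Pentacosane,629-99-2,C25 H52,94.0,31,0
Linear and branched polyethylene oligomers,Heptacosane,593-49-7,C27 H56,94.4,2,0
Linear and branched polyethylene oligomers,Octacosane,630-02-4,C28 H58,96.1,0,0
Linear and branched polyethylene oligomers,Tetraiacontane,14167-59-0,C34 H70,92.1,0,0
Linear and branched polyethylene oligomers,3-Methylpentadecane,2882-96-4,C16 H34,93.1,1,0
Linear and branched polyethylene oligomers,3-Methylheptadecane,6418-44-6,C18 H38,94.9,2,0
Linear and branched polyethylene oligomers,3-Methylnonadecane,6418-45-7,C20 H42,95.5,2,0
Linear and branched polyethylene oligomers,"2,6,10,15-Tetramethylheptadecane",54833-48-6,C21 H44,92.3,30,0
Linear and branched polyethylene oligomers,3-Methylheneicosane,6418-47-9,C22 H46,95.9,1,0
Linear and branched polyethylene oligomers,5-Methylheneicosane,25117-37-7,C22 H46,95.5,1,0
Linear and branched polyethylene oligomers,11-Methyltricosane,27538-41-6,C24 H50,95.3,38,0
Linear and branched polyethylene oligomers,2-Methyloctacosane,1560-98-1,C29 H60,95.7,43,0
Linear and branched polyethylene oligomers,5-Methylnonacosane,71868-29-6,C30 H62,94.1,9,0
Other compounds,Diphenyl sulphone,127-63-9,C12 H10 O2 S,93.0,,1
Other compounds,1-Chlorohexadecane,4860-03-1,C16 H33 Cl,94.2,21,0
Other compounds,"N,N-Dimethylpalmitylamine",112-69-6,C18 H39 N,96.1,,0
Other compounds,Galaxolide,1222-05-5,C18 H26 O,95.8,,0
Other compounds,Methyl dehydroabietate,1235-74-1,C21 H30 O2,97.6,2,0
Other compounds,Methyl abietate,127-25-3,C21 H32 O2,96.2,4,0
Other compounds,Bis(2-ethylhexyl) adipate,103-23-1,C22 H42 O4,93.5,12,1
Other compounds,Irgafos 168,31570-04-4,C42 H63 O3 P,94.7,5,1
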